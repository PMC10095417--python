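"""Compare a candidate core against known nisin variants.

Mature nisin cores are short (31-35 aa) and near-identical, so comparisons
are percent identity and p-distance on positionally aligned sequences, and
the dendrogram is a neighbor-joining tree on the p-distance matrix.  The
three cores asserted here are the ones whose sequences are unambiguous:
nisin A, nisin F, and the novel variant nisin S; further panel members are
supplied by the user as FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import SequenceRecord, read_fasta

NISIN_A = "ITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK"
NISIN_F = "ITSISLCTPGCKTGALMGCNMKTATCHCSVHVSK"
NISIN_S = "ITSYSLCTPGCKTGALMGCTMKTASCGCHVHISK"


@dataclass(frozen=True)
class VariantPanel:
    """Named mature core sequences, uniquely labelled."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("panel names must be unique")
        for name, seq in self.entries:
            if not 5 <= len(seq):
                raise ValueError(f"panel entry {name!r} is too short")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def sequence(self, name: str) -> str:
        for n, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)


def reference_panel() -> VariantPanel:
    """The packaged panel: nisin A, nisin F, nisin S mature cores."""
    with resources.as_file(
        resources.files("lanthimine.data").joinpath("nisin_cores.fasta")
    ) as path:
        records = read_fasta(path, "protein")
    return panel_from_records(records)


def panel_from_records(records: Sequence[SequenceRecord]) -> VariantPanel:
    return VariantPanel(tuple((r.identifier, r.residues) for r in records))


def percent_identity(a: str, b: str) -> float:
    """100 x matching positions / length, 2 dp; equal lengths required."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "route unequal-length variants through topology threading"
        )
    matches = sum(x == y for x, y in zip(a, b))
    return round(100.0 * matches / len(a), 2)


def substitution_list(reference: str, query: str) -> list[str]:
    """Tokens 'X<pos>Y' for every mismatching position, reference residue first."""
    if len(reference) != len(query):
        raise ValueError("sequences must be equal length")
    return [
        f"{r}{pos}{q}"
        for pos, (r, q) in enumerate(zip(reference, query), start=1)
        if r != q
    ]


def unique_residues(query_name: str, panel: VariantPanel) -> list[str]:
    """Positions where the query's residue occurs in no other panel entry."""
    query = panel.sequence(query_name)
    others = [s for n, s in panel.entries if n != query_name]
    for s in others:
        if len(s) != len(query):
            raise ValueError("panel must be positionally aligned (equal length)")
    return [
        f"{res}{pos}"
        for pos, res in enumerate(query, start=1)
        if all(other[pos - 1] != res for other in others)
    ]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    distances: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distances must be symmetric with zero diagonal")


def p_distance_matrix(panel: VariantPanel) -> DistanceMatrix:
    """Pairwise p-distances (fraction of mismatching positions)."""
    n = len(panel)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = panel.entries[i][1], panel.entries[j][1]
            if len(a) != len(b):
                raise ValueError("panel must be positionally aligned")
            d[i, j] = d[j, i] = sum(x != y for x, y in zip(a, b)) / len(a)
    return DistanceMatrix(panel.names, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei) on a distance matrix.

    Standard agglomeration on the Q-criterion, ties broken by the lowest
    index pair; negative branch lengths are clamped to zero.  The returned
    tree is unrooted (trifurcating root).  On an exactly additive metric the
    tree's path lengths reproduce the input distances.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.distances.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None  # (q, i, j) with i < j in active order
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])
        # Distances from the new node to every remaining taxon.
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - dij)
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    # Join the last three nodes at an unrooted (trifurcating) root.
    i, j, k = active
    root = TreeNode()
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    root.extend([nodes[i], nodes[j], nodes[k]])
    return root
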