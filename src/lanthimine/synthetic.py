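"""Synthetic data with known ground truth for pipeline validation.

Generators emulate the observables the pipeline consumes: a bacterial genome
with an embedded lanthipeptide precursor gene, intact-mass peak lists
consistent with the dehydration model, fragment m/z lists consistent with the
tryptic digest, and mutated variant panels.  Every generator is a pure
function of (parameters, seed), and each dataset carries a SyntheticTruth
record of exactly what was planted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .digest import build_inclusion_list
from .io_formats import PeakList, SequenceRecord, make_peaklist
from .masses import dehydration_capacity, modified_core_mass
from .variants import VariantPanel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD_TABLE = unambiguous_dna_by_id[1]
# Synonymous codons per residue, stop codons under "*".
_CODONS: dict[str, list[str]] = {}
for codon, aa in _STANDARD_TABLE.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(_STANDARD_TABLE.stop_codons)


@dataclass(frozen=True)
class SyntheticTruth:
    seed: int
    precursor: Optional[str] = None
    leader: Optional[str] = None
    core: Optional[str] = None
    minus1_residue: Optional[str] = None
    orf_start: Optional[int] = None       # 0-based half-open, forward strand
    orf_end: Optional[int] = None
    strand: Optional[str] = None
    n_dehydrations: Optional[int] = None
    true_peaks: tuple[float, ...] = field(default=())
    decoy_peaks: tuple[float, ...] = field(default=())

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def make_precursor(
    core: str, leader_len: int = 25, minus1: str = "K", seed: int = 0
) -> str:
    """A synthetic precursor: Met-initiated random leader ending in ``minus1``
    followed by the core.  Total length = leader_len + len(core)."""
    if leader_len < 5:
        raise ValueError("leader_len must be >= 5")
    rng = random.Random(seed)
    middle = "".join(rng.choice(AMINO_ACIDS) for _ in range(leader_len - 2))
    return "M" + middle + minus1 + core


def _reverse_translate(protein: str, rng: random.Random) -> str:
    codons = [rng.choice(_CODONS[aa]) for aa in protein]
    # Initiator must be a start codon; Met's only codon is ATG already.
    codons[0] = "ATG"
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def embed_cluster(
    genome_len: int,
    precursor: str,
    strand: str = "+",
    seed: int = 0,
    contig: str = "synthetic_contig",
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Random genome with the reverse-translated precursor gene planted.

    The coding sequence is preceded by an in-frame stop codon so the planted
    ORF cannot be extended leftward by chance background start codons; truth
    records exact 0-based forward-strand coordinates of start..stop.
    """
    rng = random.Random(seed)
    cds = _reverse_translate(precursor, rng)
    guard = rng.choice(_STOPS)
    cassette = guard + cds
    if strand == "-":
        cassette = str(Seq(cassette).reverse_complement())
    if genome_len < len(cassette) + 200:
        raise ValueError(
            f"genome_len {genome_len} too short for a {len(cassette)} nt insert"
        )
    background_len = genome_len - len(cassette)
    insert_at = rng.randrange(50, background_len - 50)
    background = "".join(rng.choice("ACGT") for _ in range(background_len))
    genome = background[:insert_at] + cassette + background[insert_at:]
    if strand == "+":
        orf_start = insert_at + 3  # skip the guard stop
        orf_end = orf_start + len(cds)
    else:
        orf_end = insert_at + len(cassette) - 3
        orf_start = orf_end - len(cds)
    truth = SyntheticTruth(
        seed=seed,
        precursor=precursor,
        minus1_residue=None,
        orf_start=orf_start,
        orf_end=orf_end,
        strand=strand,
    )
    record = SequenceRecord(
        identifier=contig,
        description=f"{contig} synthetic genome with planted precursor",
        residues=genome,
    )
    return record, truth


def simulate_peaks(
    core: str,
    n_dehydrations: int,
    jitter_sd: float = 0.0,
    n_decoys: int = 0,
    dropout_p: float = 0.0,
    seed: int = 0,
) -> tuple[PeakList, PeakList, SyntheticTruth]:
    """Noisy observables for a mature core with a known dehydration count.

    Returns (intact neutral-mass peaks, fragment m/z peaks, truth).  The
    intact peak is the core's average mass minus n waters; fragment peaks are
    every z=2-4 inclusion-list m/z.  Each peak gets N(0, jitter_sd) noise and
    is dropped with probability ``dropout_p``; decoys are uniform over the
    observed range +/- 50 Da.
    """
    n_ser, n_thr, _ = dehydration_capacity(core)
    if n_dehydrations > n_ser + n_thr:
        raise ValueError("n_dehydrations exceeds Ser+Thr capacity")
    rng = random.Random(seed)
    intact_true = modified_core_mass(core, n_dehydrations, "avg")
    frag_true = [t.mz for t in build_inclusion_list(core, charges=(2, 3, 4))]

    def observe(values: Sequence[float]) -> list[float]:
        out = []
        for v in values:
            if rng.random() < dropout_p:
                continue
            out.append(v + rng.gauss(0.0, jitter_sd) if jitter_sd > 0 else v)
        return out

    intact_obs = observe([intact_true])
    frag_obs = observe(frag_true)
    all_true = [intact_true] + frag_true
    lo, hi = min(all_true) - 50.0, max(all_true) + 50.0
    decoys = [rng.uniform(lo, hi) for _ in range(n_decoys)]
    # Decoys land in the fragment (m/z) list: that is where false matching
    # pressure matters for the targeted method.
    frag_obs = frag_obs + decoys

    intact_pl = make_peaklist([(v, 1.0) for v in intact_obs], "neutral_mass")
    frag_pl = make_peaklist([(v, 1.0) for v in frag_obs], "mz")
    truth = SyntheticTruth(
        seed=seed,
        core=core,
        n_dehydrations=n_dehydrations,
        true_peaks=tuple(all_true),
        decoy_peaks=tuple(decoys),
    )
    return intact_pl, frag_pl, truth


def mutate_panel(
    core: str,
    n_variants: int,
    subs_per_variant: int,
    seed: int = 0,
    reference_name: str = "reference",
) -> VariantPanel:
    """Panel of variants each differing from ``core`` at exactly
    ``subs_per_variant`` seeded positions (plus the core itself)."""
    if subs_per_variant > len(core):
        raise ValueError("subs_per_variant exceeds core length")
    rng = random.Random(seed)
    entries = [(reference_name, core)]
    for k in range(1, n_variants + 1):
        positions = rng.sample(range(len(core)), subs_per_variant)
        seq = list(core)
        for p in positions:
            seq[p] = rng.choice([aa for aa in AMINO_ACIDS if aa != core[p]])
        entries.append((f"variant_{k}", "".join(seq)))
    return VariantPanel(tuple(entries))
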