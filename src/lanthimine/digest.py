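"""In-silico tryptic digestion and targeted-MS inclusion lists.

Trypsin cleaves C-terminal to Lys/Arg except when the next residue is Pro.
For a candidate core the pipeline digests in silico, expands fixed
(carbamidomethyl-Cys) and variable (Met oxidation) modifications, computes
precursor m/z over a charge range, and emits the inclusion list a targeted
LC-MS method would be loaded with.

Charge convention: m/z = (M + z * 1.007276) / z with the bare-proton mass,
which reproduces high-resolution detected m/z values at 2 dp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .masses import PROTON, Modification, ModifiedPeptide, peptide_mass

# (residue, delta Da, label) triples; defaults match iodoacetamide alkylation
# and air oxidation of Met in a standard proteomics workflow.
ModSpec = tuple[str, float, str]


@dataclass(frozen=True)
class DigestFragment:
    """A proteolytic fragment with its 1-based inclusive span on the parent."""

    sequence: str
    span: tuple[int, int]
    missed_cleavages: int


@dataclass(frozen=True)
class InclusionTarget:
    """One row of a targeted-MS inclusion list."""

    peptide: ModifiedPeptide
    charge: int
    mz: float
    neutral_mass: float
    span: tuple[int, int]


def tryptic_digest(seq: str, max_missed: int = 0) -> list[DigestFragment]:
    """All tryptic fragments of ``seq`` with <= ``max_missed`` missed cleavages.

    Cleavage sites are after K or R unless followed by P.  Fragments are
    ordered by start position, then length; fragments with 0 missed cleavages
    tile the parent exactly.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # Cut points as 0-based indices into seq (cut after position i-1).
    cuts = [0]
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    fragments: list[DigestFragment] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            start, end = cuts[a], cuts[b]
            fragments.append(
                DigestFragment(
                    sequence=seq[start:end],
                    span=(start + 1, end),
                    missed_cleavages=b - a - 1,
                )
            )
    fragments.sort(key=lambda f: (f.span[0], len(f.sequence)))
    return fragments


def enumerate_modforms(
    frag: DigestFragment,
    fixed: Sequence[ModSpec] = (),
    variable: Sequence[ModSpec] = (),
    max_variable: int = 0,
) -> list[ModifiedPeptide]:
    """All modification forms of a fragment.

    Fixed modifications are applied to every eligible residue.  Variable
    modifications are enumerated over all position subsets of size up to
    ``max_variable`` (at most one per position).  Order is deterministic:
    ascending number of variable mods, then positions lexicographic.
    """
    if max_variable < 0:
        raise ValueError("max_variable must be >= 0")
    fixed_mods = []
    fixed_positions = set()
    for pos, residue in enumerate(frag.sequence, start=1):
        for res, delta, label in fixed:
            if residue == res:
                fixed_mods.append(Modification(pos, delta, label))
                fixed_positions.add(pos)
    # Eligible (position, spec) pairs for variable mods, skipping positions
    # already carrying a fixed mod.
    var_sites = [
        (pos, delta, label)
        for pos, residue in enumerate(frag.sequence, start=1)
        for res, delta, label in variable
        if residue == res and pos not in fixed_positions
    ]
    forms: list[ModifiedPeptide] = []
    for k in range(0, max_variable + 1):
        for combo in itertools.combinations(var_sites, k):
            mods = tuple(fixed_mods) + tuple(
                Modification(pos, delta, label) for pos, delta, label in combo
            )
            forms.append(ModifiedPeptide(frag.sequence, mods))
    return forms


def mz(neutral_mass: float, charge: int) -> float:
    """Mass-to-charge ratio of the z-fold protonated species (Th)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


# Default modification set of the targeted workflow.
FIXED_CARBAMIDOMETHYL: tuple[ModSpec, ...] = (("C", 57.02146, "Carbamidomethyl"),)
VARIABLE_OXIDATION: tuple[ModSpec, ...] = (("M", 15.994915, "Oxidation"),)


def build_inclusion_list(
    core: str,
    charges: Iterable[int] = (2, 3, 4),
    fixed: Sequence[ModSpec] = FIXED_CARBAMIDOMETHYL,
    variable: Sequence[ModSpec] = VARIABLE_OXIDATION,
    max_variable: int = 2,
    max_missed: int = 0,
) -> list[InclusionTarget]:
    """Digest -> modform enumeration -> all charges, deduplicated and sorted.

    Positional isomers with the same modification multiset have the same mass
    and collapse to one target (matching how targeted methods list one
    precursor per mass).  Output is sorted by m/z, ties by charge.
    """
    charges = sorted(set(charges))
    if not charges or charges[0] < 1 or charges[-1] > 6:
        raise ValueError("charge range must lie within [1, 6]")
    seen: set[tuple[str, tuple[str, ...], int]] = set()
    targets: list[InclusionTarget] = []
    for frag in tryptic_digest(core, max_missed):
        for form in enumerate_modforms(frag, fixed, variable, max_variable):
            neutral = peptide_mass(form, "mono")
            for z in charges:
                key = (form.sequence, form.mod_labels, z)
                if key in seen:
                    continue
                seen.add(key)
                targets.append(
                    InclusionTarget(
                        peptide=form,
                        charge=z,
                        mz=mz(neutral, z),
                        neutral_mass=neutral,
                        span=frag.span,
                    )
                )
    targets.sort(key=lambda t: (t.mz, t.charge))
    return targets


def write_inclusion_list(targets: Sequence[InclusionTarget], path) -> None:
    """Inclusion list TSV: sequence, mod_labels, z, m/z (4 dp), neutral (4 dp)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\tmod_labels\tz\tmz\tneutral_mass\n")
        for t in targets:
            labels = ";".join(t.peptide.mod_labels) or "-"
            fh.write(
                f"{t.peptide.sequence}\t{labels}\t{t.charge}\t"
                f"{t.mz:.4f}\t{t.neutral_mass:.4f}\n"
            )
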