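"""Peptide mass arithmetic for lanthipeptide maturation accounting.

Lanthipeptide maturation dehydrates Ser/Thr residues (-H2O each) before
thioether ring formation, so the secreted peptide is lighter than the
unmodified translation product by an integer number of waters.  This module
does all of the mass bookkeeping that reasoning rests on: monoisotopic and
isotope-averaged peptide masses, fixed/variable modification deltas, and the
inference of a dehydration count from an observed intact mass.

Residue masses come from pyteomics (``mass.std_aa_mass`` for monoisotopic,
``mass.std_aa_comp`` evaluated with average element masses for the average
table); nothing mass-critical is hand-typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from pyteomics import mass as _pmass

MassType = Literal["mono", "avg"]

# Monoisotopic residue masses (Da), e.g. G 57.02146, C 103.00919.
RESIDUE_MONO: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}
# Average residue masses from the same elemental compositions.
RESIDUE_AVG: dict[str, float] = {
    aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

WATER_MONO = 18.010565
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)  # 18.0153
PROTON = 1.007276

# Common fixed/variable modification deltas (Da, monoisotopic).
CARBAMIDOMETHYL = 57.02146  # iodoacetamide alkylation of Cys
OXIDATION = 15.994915       # Met oxidation


class AlphabetError(ValueError):
    """A residue outside the standard 20-letter amino-acid alphabet."""


class CapacityError(ValueError):
    """More dehydrations requested than the peptide has Ser+Thr residues."""


def _water(mass_type: MassType) -> float:
    if mass_type == "mono":
        return WATER_MONO
    if mass_type == "avg":
        return WATER_AVG
    raise ValueError(f"mass_type must be 'mono' or 'avg', got {mass_type!r}")


def _residue_table(mass_type: MassType) -> dict[str, float]:
    return RESIDUE_MONO if mass_type == "mono" else RESIDUE_AVG


@dataclass(frozen=True)
class Modification:
    """One localized mass delta: 1-based position, delta in Da, label."""

    position: int
    delta: float
    label: str


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with per-position mass deltas.

    ``mods`` holds at most one variable modification per position; fixed
    modifications are expected to have been expanded onto every eligible
    residue before construction (see ``digest.enumerate_modforms``).
    """

    sequence: str
    mods: tuple[Modification, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        n = len(self.sequence)
        for m in self.mods:
            if not 1 <= m.position <= n:
                raise ValueError(
                    f"modification position {m.position} outside 1..{n}"
                )
        positions = [m.position for m in self.mods]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one modification per position")

    @property
    def mod_labels(self) -> tuple[str, ...]:
        """Sorted multiset of modification labels (positional isomers collapse)."""
        return tuple(sorted(m.label for m in self.mods))


@dataclass(frozen=True)
class DehydrationInference:
    """Reconciliation of a deduced (unmodified) mass with an observed one.

    ``deduced - n_dehydrations * water - residual == observed`` holds exactly;
    the residual is the part of the mass difference a whole number of water
    losses cannot explain.
    """

    deduced_mass: float
    observed_mass: float
    n_dehydrations: int
    residual: float
    mass_type: MassType


def peptide_mass(peptide: ModifiedPeptide | str, mass_type: MassType = "mono") -> float:
    """Neutral (uncharged) mass of a possibly modified peptide in Da.

    Sum of residue masses plus one water plus all modification deltas.
    Protonation is deliberately not handled here; charged species live in
    :mod:`lanthimine.digest`.
    """
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide)
    table = _residue_table(mass_type)
    total = _water(mass_type)
    for i, residue in enumerate(peptide.sequence, start=1):
        try:
            total += table[residue]
        except KeyError:
            raise AlphabetError(
                f"unknown residue {residue!r} at position {i}"
            ) from None
    total += sum(m.delta for m in peptide.mods)
    return total


def infer_dehydrations(
    deduced: float, observed: float, mass_type: MassType = "avg"
) -> DehydrationInference:
    """Explain ``deduced - observed`` as n water losses plus a residual.

    n is the nearest non-negative integer number of waters; the residual is
    whatever is left and is reported, never hidden (a negative difference
    yields n = 0 with the full difference as residual).
    """
    water = _water(mass_type)
    diff = deduced - observed
    n = max(0, round(diff / water))
    residual = diff - n * water
    return DehydrationInference(
        deduced_mass=deduced,
        observed_mass=observed,
        n_dehydrations=n,
        residual=residual,
        mass_type=mass_type,
    )


def dehydration_capacity(core: str) -> tuple[int, int, int]:
    """Counts of (Ser, Thr, Cys) in a core peptide.

    Ser+Thr bounds the number of dehydrations; Cys counts the available
    thioether acceptors.
    """
    return core.count("S"), core.count("T"), core.count("C")


def modified_core_mass(
    core: str, n_dehydrations: int, mass_type: MassType = "avg"
) -> float:
    """Mass of a core peptide after ``n_dehydrations`` water losses."""
    n_ser, n_thr, _ = dehydration_capacity(core)
    capacity = n_ser + n_thr
    if n_dehydrations < 0:
        raise ValueError("n_dehydrations must be >= 0")
    if n_dehydrations > capacity:
        raise CapacityError(
            f"{n_dehydrations} dehydrations requested but core has only "
            f"{capacity} Ser+Thr residues"
        )
    return peptide_mass(core, mass_type) - n_dehydrations * _water(mass_type)


def export_constants(path) -> None:
    """Write the residue mass tables and constants as documented TSV."""
    lines = ["# residue\tmonoisotopic_Da\taverage_Da"]
    for aa in sorted(RESIDUE_MONO):
        lines.append(f"{aa}\t{RESIDUE_MONO[aa]:.6f}\t{RESIDUE_AVG[aa]:.6f}")
    lines.append(f"# water_mono\t{WATER_MONO:.6f}")
    lines.append(f"# water_avg\t{WATER_AVG:.6f}")
    lines.append(f"# proton\t{PROTON:.6f}")
    lines.append(f"# carbamidomethyl\t{CARBAMIDOMETHYL:.6f}")
    lines.append(f"# oxidation\t{OXIDATION:.6f}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
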