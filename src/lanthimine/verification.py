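"""Match theoretical targets to observed peaks; intact-mass reconciliation.

Two independent lines of mass evidence identify a candidate core as the
secreted peptide: (1) the intact mass, explained as the unmodified core minus
an integer number of waters (dehydrations), and (2) tryptic fragments from a
targeted LC-MS run, matched against the in-silico inclusion list, giving
sequence coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .digest import InclusionTarget
from .io_formats import PeakList
from .masses import (
    DehydrationInference,
    MassType,
    dehydration_capacity,
    infer_dehydrations,
    peptide_mass,
)

# Defaults: 0.02 Th suits a high-resolution orbitrap precursor scan; 0.5 Da
# suits linear-mode MALDI intact masses.
DEFAULT_MZ_TOLERANCE = 0.02
DEFAULT_INTACT_TOLERANCE = 0.5


@dataclass(frozen=True)
class MatchResult:
    target: InclusionTarget
    observed: Optional[float]
    delta: Optional[float]
    matched: bool


@dataclass(frozen=True)
class CoverageReport:
    core_length: int
    covered_positions: frozenset[int]
    coverage_pct: float


def match_targets(
    targets: Sequence[InclusionTarget],
    peaks: PeakList,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> list[MatchResult]:
    """Assign each target to the nearest peak within tolerance.

    One peak may satisfy several targets.  Ties between equidistant peaks go
    to the lower value, keeping the assignment deterministic.  Unmatched
    targets are reported with matched=False.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    results: list[MatchResult] = []
    values = peaks.values
    for target in targets:
        best: Optional[float] = None
        for v in values:  # values are sorted, so ties resolve to lower v
            if best is None or abs(v - target.mz) < abs(best - target.mz):
                best = v
        if best is not None and abs(best - target.mz) <= tolerance:
            results.append(MatchResult(target, best, best - target.mz, True))
        else:
            results.append(MatchResult(target, None, None, False))
    return results


def sequence_coverage(
    matches: Sequence[MatchResult], core_length: int
) -> CoverageReport:
    """Fraction of core positions covered by at least one matched fragment."""
    if core_length < 1:
        raise ValueError("core_length must be >= 1")
    covered: set[int] = set()
    for m in matches:
        if not m.matched:
            continue
        start, end = m.target.span
        if start < 1 or end > core_length:
            raise ValueError(
                f"matched span {m.target.span} outside [1, {core_length}]"
            )
        covered.update(range(start, end + 1))
    return CoverageReport(
        core_length=core_length,
        covered_positions=frozenset(covered),
        coverage_pct=100.0 * len(covered) / core_length,
    )


def reconcile_intact(
    peaks: PeakList,
    core: str,
    mass_type: MassType = "avg",
    max_residual: float = DEFAULT_INTACT_TOLERANCE,
) -> Optional[DehydrationInference]:
    """Explain some observed intact mass as the core minus n waters.

    Every peak is tried against the unmodified core mass; the inference with
    the smallest absolute residual wins, provided the residual is within
    ``max_residual`` and the dehydration count does not exceed the core's
    Ser+Thr capacity.  Returns None when no peak reconciles.
    """
    if peaks.value_kind != "neutral_mass":
        raise ValueError("intact reconciliation requires neutral-mass peaks")
    deduced = peptide_mass(core, mass_type)
    n_ser, n_thr, _ = dehydration_capacity(core)
    capacity = n_ser + n_thr
    best: Optional[DehydrationInference] = None
    for value in peaks.values:
        inf = infer_dehydrations(deduced, value, mass_type)
        if abs(inf.residual) > max_residual or inf.n_dehydrations > capacity:
            continue
        if best is None or abs(inf.residual) < abs(best.residual):
            best = inf
    return best
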