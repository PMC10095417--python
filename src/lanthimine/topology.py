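"""Template-based lanthionine ring-topology threading.

Natural nisin variants share a conserved fold of five thioether rings (A-E):
a dehydrated Ser or Thr (donor) linked to a Cys (acceptor).  A Ser donor
forms a lanthionine (Lan) ring; a Thr donor forms a 3-methyllanthionine
(MeLan) ring.  Rings D and E intertwine (overlapping spans); residues 20-22
form the flexible hinge between the lipid-II-binding N-domain and the
pore-forming C-domain.

Because the fold is conserved, a new variant's topology can be predicted by
threading its core onto the nisin A template: each template bridge maps to
the same positions, and residue classes are validated at the mapped donor and
acceptor sites.  The result is a structural hypothesis, not a chemically
verified assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

NISIN_A_CORE = "ITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK"


@dataclass(frozen=True)
class Bridge:
    ring_label: str
    donor_pos: int      # 1-based
    acceptor_pos: int   # 1-based
    type: str           # "Lan" or "MeLan"


@dataclass(frozen=True)
class TemplateTopology:
    name: str
    core: str
    bridge_positions: tuple[tuple[str, int, int], ...]
    hinge_positions: tuple[int, int, int]


NISIN_A_TEMPLATE = TemplateTopology(
    name="nisin A",
    core=NISIN_A_CORE,
    bridge_positions=(
        ("A", 3, 7),
        ("B", 8, 11),
        ("C", 13, 19),
        ("D", 23, 26),
        ("E", 25, 28),
    ),
    hinge_positions=(20, 21, 22),
)


@dataclass(frozen=True)
class RingTopology:
    bridges: tuple[Bridge, ...]
    template_name: str
    # Ser/Thr positions outside any ring: dehydratable but not assigned a
    # Dha/Dhb identity by threading alone.
    unassigned_dehydratable: tuple[int, ...]


class ThreadingError(ValueError):
    """Mapped donor/acceptor positions have the wrong residue class."""


def _alignment_offset(core: str, template_core: str) -> int:
    """Gapless offset of ``core`` relative to the template, for variants whose
    length differs from the template's.  Anchors on maximum identity over the
    overlap, preferring the smallest |offset| on ties (the ring-A region is
    near-invariant across natural variants, so identity anchoring pins it)."""
    best_offset, best_score = 0, -1
    span = abs(len(core) - len(template_core)) + 1
    candidates = sorted(range(-span, span + 1), key=lambda o: (abs(o), o))
    for offset in candidates:
        score = sum(
            1
            for i, ch in enumerate(template_core)
            if 0 <= i + offset < len(core) and core[i + offset] == ch
        )
        if score > best_score:
            best_offset, best_score = offset, score
    return best_offset


def thread_template(
    core: str, template: TemplateTopology = NISIN_A_TEMPLATE
) -> RingTopology:
    """Map the template's bridges onto ``core`` and classify each ring.

    Equal-length cores map positionally; shorter/longer variants are placed
    by a gapless-offset alignment.  Raises ThreadingError naming every ring
    whose mapped donor is not Ser/Thr or whose acceptor is not Cys.
    """
    offset = 0
    if len(core) != len(template.core):
        offset = _alignment_offset(core, template.core)
    bridges: list[Bridge] = []
    violations: list[str] = []
    ring_positions: set[int] = set()
    for label, donor_t, acceptor_t in template.bridge_positions:
        donor, acceptor = donor_t + offset, acceptor_t + offset
        if not (1 <= donor <= len(core) and 1 <= acceptor <= len(core)):
            violations.append(f"ring {label}: mapped outside the core")
            continue
        d_res, a_res = core[donor - 1], core[acceptor - 1]
        if d_res not in "ST" or a_res != "C":
            violations.append(
                f"ring {label}: donor {d_res}{donor} / acceptor {a_res}{acceptor}"
            )
            continue
        bridges.append(
            Bridge(
                ring_label=label,
                donor_pos=donor,
                acceptor_pos=acceptor,
                type="Lan" if d_res == "S" else "MeLan",
            )
        )
        ring_positions.update((donor, acceptor))
    if violations:
        raise ThreadingError(
            "template threading failed: " + "; ".join(violations)
        )
    unassigned = tuple(
        pos
        for pos, res in enumerate(core, start=1)
        if res in "ST" and pos not in ring_positions
    )
    return RingTopology(
        bridges=tuple(bridges),
        template_name=template.name,
        unassigned_dehydratable=unassigned,
    )


def hinge_residues(
    core: str, template: TemplateTopology = NISIN_A_TEMPLATE
) -> str:
    """Residues at the template's hinge positions (20-22 for nisin)."""
    if len(core) < max(template.hinge_positions):
        raise ValueError(
            f"core of length {len(core)} has no position "
            f"{max(template.hinge_positions)}"
        )
    return "".join(core[p - 1] for p in template.hinge_positions)


def topology_as_dict(topo: RingTopology) -> dict:
    """JSON-ready representation of a predicted topology."""
    return {
        "template": topo.template_name,
        "bridges": [
            {
                "ring": b.ring_label,
                "donor": b.donor_pos,
                "acceptor": b.acceptor_pos,
                "type": b.type,
            }
            for b in topo.bridges
        ],
        "unassigned_dehydratable": list(topo.unassigned_dehydratable),
    }


def topology_schematic(core: str, topo: RingTopology) -> str:
    """One-line schematic: ring letters under their donor..acceptor spans."""
    line = ["."] * len(core)
    for b in topo.bridges:
        for pos in range(b.donor_pos, b.acceptor_pos + 1):
            line[pos - 1] = b.ring_label
    return core + "\n" + "".join(line)
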