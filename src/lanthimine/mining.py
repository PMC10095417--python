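"""Genome mining for nisin-family precursor genes.

Candidate precursors are found by six-frame ORF extraction followed by
similarity search against a panel of known mature cores: a precursor is an
ORF whose protein contains a window highly similar to a known core, with the
window-to-C-terminus suffix taken as the core and the prefix as the leader
peptide (nisin precursors are leader+core with no follower).  Flanking ORFs
are annotated against reference biosynthesis proteins, with a truncation flag
for frameshifted pseudogene products.

Coordinates are 0-based half-open on the forward strand internally; reports
use 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .io_formats import SequenceRecord
from .variants import VariantPanel

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MIN_IDENTITY_PCT = 40.0
DEFAULT_MIN_PROTEIN_LEN = 30
DEFAULT_TRUNCATION_RATIO = 0.8


@dataclass(frozen=True)
class OpenReadingFrame:
    contig: str
    start: int   # 0-based, forward strand
    end: int     # half-open; includes the stop codon
    strand: str  # '+' or '-'
    frame: int   # 0-2 on the scanned strand
    protein: str # no terminal stop; initiator codon translated as Met

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with coordinates")


@dataclass(frozen=True)
class PrecursorCandidate:
    orf: OpenReadingFrame
    best_reference: str
    core_identity_pct: float
    leader: str
    core: str

    @property
    def minus1_residue(self) -> str:
        return self.leader[-1] if self.leader else ""


@dataclass(frozen=True)
class ClusterAnnotation:
    orf: OpenReadingFrame
    assigned_family: str
    identity_pct: float
    length_ratio: float
    truncated: bool


def _translate(codons: Sequence[str]) -> str:
    # Initiator codon reads as Met regardless of ATG/GTG/TTG.
    body = "".join(str(Seq(c).translate()) for c in codons[1:])
    return "M" + body


def _scan_strand(
    seq: str, contig: str, strand: str, min_protein_len: int, genome_len: int
) -> list[OpenReadingFrame]:
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        start_idx: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start_idx is None and codon in START_CODONS:
                start_idx = i
            elif codon in STOP_CODONS:
                if start_idx is not None:
                    s, e = start_idx, i + 3
                    protein_len = (e - s) // 3 - 1
                    if protein_len >= min_protein_len:
                        codons = [seq[j : j + 3] for j in range(s, e - 3, 3)]
                        if strand == "+":
                            fwd = (s, e)
                        else:
                            fwd = (genome_len - e, genome_len - s)
                        orfs.append(
                            OpenReadingFrame(
                                contig=contig,
                                start=fwd[0],
                                end=fwd[1],
                                strand=strand,
                                frame=frame,
                                protein=_translate(codons),
                            )
                        )
                start_idx = None
    return orfs


def six_frame_orfs(
    genome: SequenceRecord, min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN
) -> list[OpenReadingFrame]:
    """Every maximal start-to-stop ORF on both strands, standard code.

    Maximal means the ORF runs from the first start codon after the previous
    in-frame stop to the next stop.  Start codons: ATG/GTG/TTG; reverse-strand
    ORFs are reported with forward-strand coordinates.
    """
    seq = genome.residues
    if set(seq) - set("ACGTN"):
        raise ValueError(
            f"record {genome.identifier!r} is not a plain nucleotide sequence"
        )
    if min_protein_len < 10:
        raise ValueError("min_protein_len must be >= 10")
    fwd = _scan_strand(seq, genome.identifier, "+", min_protein_len, len(seq))
    rc = str(Seq(seq).reverse_complement())
    rev = _scan_strand(rc, genome.identifier, "-", min_protein_len, len(seq))
    orfs = fwd + rev
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _window_identity(window: str, reference: str) -> float:
    matches = sum(a == b for a, b in zip(window, reference))
    return 100.0 * matches / len(reference)


def score_precursors(
    orfs: Sequence[OpenReadingFrame],
    panel: VariantPanel,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
) -> list[PrecursorCandidate]:
    """Score ORFs against a panel of known mature cores.

    For each ORF, the best ungapped equal-length window match of any panel
    core is found; an ORF qualifies when that identity meets the threshold.
    The matched window's start splits the protein: prefix = leader, suffix to
    the C-terminus = core.  Output sorted by identity desc, then contig and
    start asc.
    """
    if len(panel) == 0:
        raise ValueError("reference panel must be non-empty")
    candidates: list[PrecursorCandidate] = []
    for orf in orfs:
        best: Optional[tuple[float, int, str]] = None  # (identity, win_start, ref)
        for ref_name, ref_core in panel.entries:
            w = len(ref_core)
            if w > len(orf.protein):
                continue
            for s in range(len(orf.protein) - w + 1):
                ident = _window_identity(orf.protein[s : s + w], ref_core)
                key = (-ident, s, ref_name)
                if best is None or key < (-best[0], best[1], best[2]):
                    best = (ident, s, ref_name)
        if best is None or best[0] < min_identity_pct:
            continue
        ident, win_start, ref_name = best
        candidates.append(
            PrecursorCandidate(
                orf=orf,
                best_reference=ref_name,
                core_identity_pct=round(ident, 2),
                leader=orf.protein[:win_start],
                core=orf.protein[win_start:],
            )
        )
    candidates.sort(
        key=lambda c: (-c.core_identity_pct, c.orf.contig, c.orf.start)
    )
    return candidates


def split_leader_core(candidate: PrecursorCandidate) -> tuple[str, str, str, str]:
    """Return (leader, core, -1 residue, cleavage class).

    The -1 residue is the last leader residue before the cleavage site; its
    class is 'arginine' (most nisins), 'lysine' (nisin S, nisin O1-3) or
    'other'.
    """
    if not candidate.leader:
        raise ValueError(
            "degenerate candidate: matched core window starts at the N-terminus"
        )
    minus1 = candidate.leader[-1]
    cls = {"R": "arginine", "K": "lysine"}.get(minus1, "other")
    return candidate.leader, candidate.core, minus1, cls


def _global_identity(a: str, b: str) -> float:
    """Ungapped head-to-head identity; the shorter sequence is implicitly
    padded with mismatches (denominator = longer length)."""
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / max(len(a), len(b))


def annotate_cluster(
    orfs: Sequence[OpenReadingFrame],
    protein_refs: Sequence[SequenceRecord],
    family_threshold_pct: float = DEFAULT_MIN_IDENTITY_PCT,
    truncation_ratio: float = DEFAULT_TRUNCATION_RATIO,
) -> list[ClusterAnnotation]:
    """Assign each ORF to the best-matching reference biosynthesis protein.

    An ORF markedly shorter than its assigned reference (length ratio below
    ``truncation_ratio``) is flagged truncated — the signature of a
    frameshifted pseudogene product.
    """
    if not protein_refs:
        raise ValueError("protein reference set must be non-empty")
    annotations: list[ClusterAnnotation] = []
    for orf in orfs:
        best_name, best_ident, best_ratio = "unassigned", 0.0, 0.0
        for ref in protein_refs:
            ident = _global_identity(orf.protein, ref.residues)
            if ident > best_ident:
                best_name = ref.identifier
                best_ident = ident
                best_ratio = len(orf.protein) / len(ref.residues)
        if best_ident < family_threshold_pct:
            annotations.append(
                ClusterAnnotation(orf, "unassigned", round(best_ident, 2), 0.0, False)
            )
        else:
            annotations.append(
                ClusterAnnotation(
                    orf,
                    best_name,
                    round(best_ident, 2),
                    best_ratio,
                    best_ratio < truncation_ratio,
                )
            )
    return annotations
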