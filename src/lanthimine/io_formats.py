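"""File I/O: FASTA, peak-list TSV, inclusion-list TSV, Newick.

Everything the pipeline reads or writes passes through here so formats stay
dialect-explicit and round-trips are bit-stable.  FASTA goes through
Biopython; Newick through scikit-bio's TreeNode.  Peak lists are plain
two-column TSV (value, intensity) because the upstream study reports only
final masses and m/z values, not vendor spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

Alphabet = Literal["nucleotide", "protein"]

# IUPAC ambiguity codes allowed for nucleotides; X allowed for protein.
_NUC_CHARS = set("ACGTUNRYSWKMBDHV")
_PROT_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """Structurally malformed input file."""


class AlphabetError(ValueError):
    """Sequence characters inconsistent with the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    identifier: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        if not self.residues:
            raise ValueError("residues must be non-empty")


def _check_alphabet(record: SequenceRecord, alphabet: Alphabet) -> None:
    allowed = _NUC_CHARS if alphabet == "nucleotide" else _PROT_CHARS
    for ch in record.residues:
        if ch not in allowed:
            raise AlphabetError(
                f"character {ch!r} in record {record.identifier!r} is not a "
                f"valid {alphabet} symbol"
            )


def read_fasta(path, alphabet: Alphabet = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, upper-cased and validated.

    The identifier is the first whitespace-delimited token of the header;
    the full header is kept as the description.  Multi-line sequences are
    concatenated.
    """
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        rec = SequenceRecord(
            identifier=bio.id,
            description=bio.description,
            residues=str(bio.seq).upper(),
        )
        _check_alphabet(rec, alphabet)
        records.append(rec)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bios = [
        _BioRecord(Seq(r.residues), id=r.identifier, description=r.description)
        for r in records
    ]
    # Biopython writes `id description`; when description already starts with
    # the id (as read_fasta produces) strip the duplication.
    for b, r in zip(bios, records):
        if r.description.startswith(r.identifier):
            b.description = r.description[len(r.identifier):].strip()
    SeqIO.write(bios, str(path), "fasta")


ValueKind = Literal["neutral_mass", "mz"]


@dataclass(frozen=True)
class PeakList:
    """Observed peaks, sorted ascending by value.

    ``value_kind`` records whether values are neutral masses in Da (intact
    MALDI convention) or mass-to-charge ratios in Th (LC-MS precursor space);
    the two are never mixed in one list.
    """

    peaks: tuple[tuple[float, float], ...]
    value_kind: ValueKind

    def __post_init__(self) -> None:
        for v, inten in self.peaks:
            if v <= 0:
                raise ValueError(f"peak value must be positive, got {v}")
            if inten < 0:
                raise ValueError(f"intensity must be >= 0, got {inten}")
        values = [v for v, _ in self.peaks]
        if values != sorted(values):
            raise ValueError("peaks must be sorted ascending by value")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for v, _ in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def make_peaklist(
    pairs: Iterable[tuple[float, float]], value_kind: ValueKind
) -> PeakList:
    """Build a PeakList from unsorted (value, intensity) pairs."""
    return PeakList(tuple(sorted(pairs, key=lambda p: p[0])), value_kind)


def read_peaklist(path, value_kind: ValueKind) -> PeakList:
    """Read a peak-list TSV: value [TAB intensity], '#' comment lines skipped.

    A missing intensity column defaults to 1.0.
    """
    pairs: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                value = float(fields[0])
                intensity = float(fields[1]) if len(fields) > 1 else 1.0
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric peak entry {line!r}"
                ) from None
            if value <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive value {value}")
            pairs.append((value, intensity))
    if not pairs:
        logger.warning("peak list %s is empty after comments", path)
    return make_peaklist(pairs, value_kind)


def write_peaklist(peaks: PeakList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# value ({peaks.value_kind})\tintensity\n")
        for v, inten in peaks.peaks:
            fh.write(f"{v:.4f}\t{inten:g}\n")


def write_newick(tree, path) -> None:
    """Serialize a scikit-bio TreeNode as Newick with branch lengths.

    Requires >= 2 uniquely-labelled leaves.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(tips)) != len(tips):
        raise ValueError(f"duplicate leaf labels in tree: {sorted(tips)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    tree.write(str(path), format="newick")


def read_newick(path):
    """Parse a Newick file into a scikit-bio TreeNode."""
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
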