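"""Core sequence types, FASTA / BLAST-tabular readers and pairwise alignment.

The alignment backend is Biopython's :class:`Bio.Align.PairwiseAligner`
configured for global Needleman-Wunsch with BLOSUM62 and affine gap
penalties (open 11, extend 1), i.e. the default protein scoring of BLAST.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .tables import AMBIGUOUS_AA, STANDARD_AA

__all__ = [
    "ProteinRecord",
    "BlastHit",
    "PairwiseAlignment",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "align_pair",
    "default_aligner",
]


class ParseError(ValueError):
    """Raised for malformed FASTA or BLAST tabular input."""


_VALID_CHARS = frozenset(STANDARD_AA) | AMBIGUOUS_AA


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """An identified, validated amino-acid sequence.

    ``flagged`` marks records that contain tolerated ambiguity codes
    (only produced by the tolerant alphabet policy).
    """

    id: str
    sequence: str
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ParseError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cleaned(self) -> str:
        """Sequence with ambiguity codes removed."""
        return "".join(c for c in self.sequence if c in STANDARD_AA)


@dataclasses.dataclass(frozen=True)
class BlastHit:
    """One line of 12-column BLAST tabular output (optionally with lengths)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    query_length: int | None = None
    subject_length: int | None = None
    percent_similarity: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for hit {self.query_id}->{self.subject_id}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if self.percent_similarity is not None and not (
            self.percent_identity <= self.percent_similarity <= 100
        ):
            raise ValueError("need identity <= similarity <= 100")


@dataclasses.dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two protein sequences."""

    seq_a_gapped: str
    seq_b_gapped: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.seq_a_gapped) != len(self.seq_b_gapped):
            raise ValueError("gapped rows differ in length")
        for a, b in zip(self.seq_a_gapped, self.seq_b_gapped):
            if a == "-" and b == "-":
                raise ValueError("column gapped in both rows")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.seq_a_gapped, self.seq_b_gapped)

    @property
    def aligned_columns(self) -> int:
        """Columns where neither row is a gap."""
        return sum(1 for a, b in self.columns() if a != "-" and b != "-")

    @property
    def identical_columns(self) -> int:
        return sum(1 for a, b in self.columns() if a == b and a != "-")

    @property
    def identity_fraction(self) -> float:
        n = self.aligned_columns
        return self.identical_columns / n if n else 0.0

    def coverage(self, which: Literal["a", "b"]) -> float:
        """Aligned (non-gap-pair) columns as a fraction of one row's length."""
        row = self.seq_a_gapped if which == "a" else self.seq_b_gapped
        length = sum(1 for c in row if c != "-")
        return self.aligned_columns / length if length else 0.0

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(self.seq_b_gapped, self.seq_a_gapped, self.score)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet_policy: Literal["strict", "tolerant"] = "strict") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    In ``strict`` mode any tolerated ambiguity code raises; in ``tolerant``
    mode such records are returned with ``flagged=True``.  Characters outside
    the standard alphabet plus the tolerated set always raise.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: FASTA entry without a header token")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        ambiguous = set(seq) & AMBIGUOUS_AA
        if ambiguous and alphabet_policy == "strict":
            raise ParseError(
                f"{path}: record {rec.id!r} contains non-standard residues "
                f"{sorted(ambiguous)} (strict alphabet policy)"
            )
        records.append(ProteinRecord(rec.id, seq, flagged=bool(ambiguous)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Read 12-column BLAST tabular output (``-outfmt 6``).

    Two optional trailing columns are interpreted as query and subject
    lengths; a third as percent positives (similarity).
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected >= 12 columns, got {len(parts)}")
            try:
                hit = BlastHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bit_score=float(parts[11]),
                    query_length=int(parts[12]) if len(parts) > 12 else None,
                    subject_length=int(parts[13]) if len(parts) > 13 else None,
                    percent_similarity=float(parts[14]) if len(parts) > 14 else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def default_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _blosum_safe(seq: str) -> str:
    # BLOSUM62 ships rows for B, Z, X but not U, J, O.
    return seq.replace("U", "X").replace("J", "X").replace("O", "X")


def align_pair(a: ProteinRecord, b: ProteinRecord, aligner: Align.PairwiseAligner | None = None) -> PairwiseAlignment:
    """Globally align two protein records.

    Identity is reported over aligned (non-gap-pair) columns.  The first
    optimal alignment under Biopython's deterministic traceback order is
    returned, so equal inputs give equal outputs.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = default_aligner()
    aln = aligner.align(_blosum_safe(a.sequence), _blosum_safe(b.sequence))[0]
    ga, gb = _gapped_rows(a.sequence, b.sequence, aln.aligned)
    return PairwiseAlignment(ga, gb, float(aln.score))


def _gapped_rows(sa: str, sb: str, aligned) -> tuple[str, str]:
    """Reconstruct gapped rows from PairwiseAligner aligned blocks."""
    blocks_a, blocks_b = aligned
    ra: list[str] = []
    rb: list[str] = []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        # unaligned stretches before this block -> gaps against the other row
        if a0 > pa:
            ra.append(sa[pa:a0])
            rb.append("-" * (a0 - pa))
        if b0 > pb:
            ra.append("-" * (b0 - pb))
            rb.append(sb[pb:b0])
        ra.append(sa[a0:a1])
        rb.append(sb[b0:b1])
        pa, pb = a1, b1
    if pa < len(sa):
        ra.append(sa[pa:])
        rb.append("-" * (len(sa) - pa))
    if pb < len(sb):
        ra.append("-" * (len(sb) - pb))
        rb.append(sb[pb:])
    return "".join(ra), "".join(rb)


def write_alignment_fasta(aln: PairwiseAlignment, ids: tuple[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ids[0]}\n{aln.seq_a_gapped}\n>{ids[1]}\n{aln.seq_b_gapped}\n")
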