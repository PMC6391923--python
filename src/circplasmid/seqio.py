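"""Shared data model and IO for the plasmidome pipeline.

All coordinates are 0-based half-open internally.  SAM (1-based) and BLAST
tabular (1-based inclusive) coordinates are converted at the boundary, once,
so no downstream code ever reasons about off-by-ones.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A record in an input file violates its format contract."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _normalize_seq(raw: str, record_name: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FormatError(f"record {record_name!r}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {record_name!r}: non-IUPAC characters {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class Scaffold:
    """An assembled sequence; ``coverage`` is mean per-base read depth."""

    id: str
    seq: str
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("scaffold with empty id")
        object.__setattr__(self, "seq", _normalize_seq(self.seq, self.id))
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"scaffold {self.id!r}: negative coverage")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairedAlignment:
    """Both mates of one read pair placed on one scaffold.

    Mate intervals are 0-based half-open on the scaffold; strands are
    '+' / '-'.
    """

    read_id: str
    scaffold_id: str
    m1_start: int
    m1_end: int
    m1_strand: str
    m2_start: int
    m2_end: int
    m2_strand: str

    def __post_init__(self) -> None:
        for s, e in ((self.m1_start, self.m1_end), (self.m2_start, self.m2_end)):
            if not (0 <= s < e):
                raise ValueError(
                    f"pair {self.read_id!r}: invalid mate interval [{s},{e})"
                )
        for strand in (self.m1_strand, self.m2_strand):
            if strand not in ("+", "-"):
                raise ValueError(f"pair {self.read_id!r}: bad strand {strand!r}")


@dataclass(frozen=True)
class TabularHit:
    """One row of 12-column tabular alignment output (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError(f"hit {self.query_id!r}: aln_len < 1")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(
                f"hit {self.query_id!r}: pct_identity {self.pct_identity} outside [0,100]"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id!r}: negative E-value")


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and scoring constants for circular-scaffold detection.

    Criterion thresholds follow the published wording: scaffold length
    strictly > ``min_scaffold_bp``; terminal overlap strictly >
    ``min_overlap_bp`` with E <= ``max_evalue``; at least
    ``min_junction_pairs`` read pairs with mates wholly inside the two
    terminal ``end_window_bp`` windows.
    """

    min_scaffold_bp: int = 2000        # exclusive: 2,000 bp fails
    min_overlap_bp: int = 34           # exclusive: 34 bp fails
    max_evalue: float = 1e-5
    end_window_bp: int = 500           # inclusive window
    min_junction_pairs: int = 2        # "at least two"
    search_window_bp: int = 1000
    # Karlin-Altschul E = K * m * n * exp(-lambda * S), ungapped form.
    ka_lambda: float = 1.28
    ka_k: float = 0.46
    match_score: int = 1
    mismatch_score: int = -2
    gap_open_score: int = -2
    gap_extend_score: int = -2
    # strict: start-proximal mate on '-', end-proximal on '+' (FR pair
    # spanning the circular junction); permissive mode ignores orientation.
    require_junction_orientation: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_scaffold_bp",
            "min_overlap_bp",
            "max_evalue",
            "end_window_bp",
            "min_junction_pairs",
            "search_window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectionParams.{name} must be positive")
        if self.search_window_bp < self.min_overlap_bp:
            raise ValueError("search_window_bp must be >= min_overlap_bp")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[Scaffold]:
    """Read scaffolds from FASTA; normalizes case and maps U->T.

    Raises :class:`FormatError` on duplicate ids, empty sequences or
    non-IUPAC characters, naming the offending record.
    """
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        if not record.id:
            raise FormatError(f"{path}: record with empty header")
        if record.id in seen:
            raise FormatError(f"{path}: duplicate scaffold id {record.id!r}")
        seen.add(record.id)
        scaffolds.append(Scaffold(id=record.id, seq=str(record.seq)))
    return scaffolds


def write_fasta(
    scaffolds: Iterable[Scaffold],
    path: str | os.PathLike,
    line_width: int = 70,
) -> None:
    """Write scaffolds as FASTA in input order."""
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.id}\n")
            for i in range(0, sc.length, line_width):
                fh.write(sc.seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits
# ---------------------------------------------------------------------------

_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def parse_tabular_hits(path: str | os.PathLike) -> list[TabularHit]:
    """Parse a 12-column, headerless, tab-separated alignment table."""
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                typed = [cast(v) for cast, v in zip(_HIT_TYPES, fields)]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(TabularHit(*typed))
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.aln_len,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end,
                        h.s_start, h.s_end, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Paired alignments: SAM subset and internal TSV dialect
# ---------------------------------------------------------------------------

PAIR_TSV_COLUMNS = (
    "read_id", "scaffold_id",
    "m1_start", "m1_end", "m1_strand",
    "m2_start", "m2_end", "m2_strand",
)


@dataclass
class PairParseResult:
    pairs: list[PairedAlignment] = field(default_factory=list)
    cross_scaffold: int = 0
    orphans: int = 0


def parse_paired_alignments(
    path: str | os.PathLike, dialect: str = "sam-subset"
) -> PairParseResult:
    """Parse read-pair placements.

    ``sam-subset``: plain-text SAM; mates are paired by identical QNAME;
    only primary alignments are used; 1-based POS converted to 0-based
    half-open via the CIGAR reference span.  ``internal-tsv``: the
    repository's 8-column dialect (header row, columns
    ``PAIR_TSV_COLUMNS``), already 0-based half-open.

    Cross-scaffold pairs and orphan mates are tallied and excluded from
    the junction-eligible pair list.
    """
    if dialect in ("sam-subset", "sam"):
        return _parse_sam_pairs(path)
    if dialect in ("internal-tsv", "tsv"):
        return _parse_tsv_pairs(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _parse_sam_pairs(path: str | os.PathLike) -> PairParseResult:
    result = PairParseResult()
    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            by_name.setdefault(rec.query_name, []).append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    for name, mates in by_name.items():
        if len(mates) < 2:
            result.orphans += 1
            continue
        if len(mates) > 2:
            raise FormatError(
                f"{path}: read {name!r} has {len(mates)} primary alignments"
            )
        (r1, s1, e1, st1), (r2, s2, e2, st2) = mates
        if r1 != r2:
            result.cross_scaffold += 1
            continue
        result.pairs.append(
            PairedAlignment(name, r1, s1, e1, st1, s2, e2, st2)
        )
    return result


def _parse_tsv_pairs(path: str | os.PathLike) -> PairParseResult:
    result = PairParseResult()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PAIR_TSV_COLUMNS:
            raise FormatError(f"{path}: bad TSV header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns")
            result.pairs.append(
                PairedAlignment(
                    f[0], f[1],
                    int(f[2]), int(f[3]), f[4],
                    int(f[5]), int(f[6]), f[7],
                )
            )
    return result


def write_paired_alignments_tsv(
    pairs: Iterable[PairedAlignment], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_TSV_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.read_id, p.scaffold_id,
                        p.m1_start, p.m1_end, p.m1_strand,
                        p.m2_start, p.m2_end, p.m2_strand,
                    )
                )
                + "\n"
            )
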