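"""Three-criterion detection of complete circular plasmids among scaffolds.

A linearized circular molecule leaves two signatures in an assembly: a
terminal direct repeat (the assembler walks past the origin and re-emits the
start of the circle), and read pairs whose fragment spans the circular
junction, which map with mates near opposite ends of the linear scaffold.
A scaffold is called circular when all three criteria hold:

(i)   scaffold length strictly greater than ``min_scaffold_bp`` (2 kb);
(ii)  a terminal end-overlap in forward/forward orientation strictly longer
      than ``min_overlap_bp`` (34 bp) with Karlin-Altschul E-value at most
      ``max_evalue`` (1e-5);
(iii) at least ``min_junction_pairs`` (2) read pairs with one mate wholly
      inside each terminal ``end_window_bp`` (500 bp) window.

The overlap search runs a local (Smith-Waterman) alignment between the
first and last ``search_window_bp`` of the scaffold, match +1 / mismatch -2,
gaps -2; the E-value is computed from the raw score in the ungapped
Karlin-Altschul form E = K * m * n * exp(-lambda * S) with m, n the window
lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import DetectionParams, PairedAlignment, Scaffold

__all__ = [
    "EndOverlap",
    "CircularCall",
    "find_end_overlap",
    "count_junction_pairs",
    "call_circular",
    "circularize",
    "detect_all",
]


@dataclass(frozen=True)
class EndOverlap:
    """Best terminal direct-repeat alignment between a scaffold's ends.

    ``prefix_range`` and ``suffix_range`` are 0-based half-open intervals in
    scaffold coordinates covering the two copies of the repeat, both on the
    forward strand.
    """

    length: int          # alignment columns (matches + mismatches + gaps)
    identity: float      # percent of columns that are identities
    score: float
    evalue: float
    prefix_range: tuple[int, int]
    suffix_range: tuple[int, int]


@dataclass(frozen=True)
class CircularCall:
    """Per-scaffold circularity decision with the evidence behind it."""

    scaffold_id: str
    length: int
    coverage: Optional[float]
    passed_length: bool
    passed_overlap: bool
    passed_pairs: bool
    overlap: Optional[EndOverlap]
    n_junction_pairs: int
    is_circular: bool
    circular_seq: Optional[str]

    @property
    def circular_length(self) -> Optional[int]:
        return None if self.circular_seq is None else len(self.circular_seq)


def _make_aligner(params: DetectionParams) -> Align.PairwiseAligner:
    # N counts as a mismatch against everything, including N.
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                matrix[a, b] = params.match_score
            else:
                matrix[a, b] = params.mismatch_score
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open_score
    aligner.extend_gap_score = params.gap_extend_score
    return aligner


def karlin_altschul_evalue(
    score: float, m: int, n: int, params: DetectionParams
) -> float:
    return params.ka_k * m * n * math.exp(-params.ka_lambda * score)


def find_end_overlap(
    scaffold: Scaffold, params: DetectionParams | None = None
) -> Optional[EndOverlap]:
    """Best-scoring forward/forward local alignment between the two ends.

    The search windows are the first and last ``search_window_bp`` of the
    scaffold, truncated to floor(L/2) for short scaffolds so the windows
    never overlap.  Returns ``None`` when no positive-scoring alignment
    reaches the E-value threshold (absence is a value, not an error).
    """
    params = params or DetectionParams()
    L = scaffold.length
    w = min(params.search_window_bp, L // 2)
    if w < 1:
        return None
    prefix = scaffold.seq[:w]
    suffix = scaffold.seq[L - w :]

    aligner = _make_aligner(params)
    score = aligner.score(prefix, suffix)
    if score <= 0:
        return None
    evalue = karlin_altschul_evalue(score, w, w, params)
    if evalue > params.max_evalue:
        return None

    aln = aligner.align(prefix, suffix)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    blocks = aln.aligned
    p_start, p_end = int(blocks[0][0][0]), int(blocks[0][-1][1])
    s_start, s_end = int(blocks[1][0][0]), int(blocks[1][-1][1])
    return EndOverlap(
        length=int(columns),
        identity=identity,
        score=float(score),
        evalue=evalue,
        prefix_range=(p_start, p_end),
        suffix_range=(L - w + s_start, L - w + s_end),
    )


def count_junction_pairs(
    pairs: Sequence[PairedAlignment],
    scaffold: Scaffold,
    params: DetectionParams | None = None,
) -> int:
    """Count read pairs with mates wholly inside the two terminal windows.

    A pair counts when one mate lies wholly within [0, end_window_bp) and
    the other wholly within [L - end_window_bp, L).  In strict mode the
    start-proximal mate must be on '-' and the end-proximal mate on '+',
    the orientation an FR fragment spanning the circular junction produces
    on the linearized scaffold.  Each pair counts at most once.
    """
    params = params or DetectionParams()
    L = scaffold.length
    win = params.end_window_bp
    n = 0
    for pair in pairs:
        if pair.scaffold_id != scaffold.id:
            raise ValueError(
                f"pair {pair.read_id!r} maps to {pair.scaffold_id!r}, "
                f"not {scaffold.id!r}"
            )
        mates = (
            (pair.m1_start, pair.m1_end, pair.m1_strand),
            (pair.m2_start, pair.m2_end, pair.m2_strand),
        )
        for a, b in ((0, 1), (1, 0)):
            s0, e0, st0 = mates[a]   # candidate start-proximal mate
            s1, e1, st1 = mates[b]   # candidate end-proximal mate
            if e0 <= win and s1 >= L - win and e1 <= L:
                if not params.require_junction_orientation or (
                    st0 == "-" and st1 == "+"
                ):
                    n += 1
                    break
    return n


def circularize(scaffold: Scaffold, overlap: EndOverlap) -> str:
    """Trim the suffix copy of the terminal repeat, closing the circle.

    The returned string is the circular unit in the scaffold's frame:
    scaffold sequence with the bases covered by ``overlap.suffix_range``
    removed.  For an exact terminal repeat X + Y + X this returns X + Y.
    """
    s, e = overlap.suffix_range
    L = scaffold.length
    if not (0 <= s < e <= L):
        raise ValueError(
            f"scaffold {scaffold.id!r}: overlap suffix range [{s},{e}) "
            f"inconsistent with length {L}"
        )
    result = scaffold.seq[:s] + scaffold.seq[e:]
    if not result:
        raise ValueError(
            f"scaffold {scaffold.id!r}: trimming the terminal repeat leaves "
            "an empty circle"
        )
    return result


def call_circular(
    scaffold: Scaffold,
    overlap: Optional[EndOverlap],
    n_junction_pairs: int,
    params: DetectionParams | None = None,
) -> CircularCall:
    """Combine the three criteria into a circularity decision."""
    params = params or DetectionParams()
    passed_length = scaffold.length > params.min_scaffold_bp
    passed_overlap = (
        overlap is not None
        and overlap.length > params.min_overlap_bp
        and overlap.evalue <= params.max_evalue
    )
    passed_pairs = n_junction_pairs >= params.min_junction_pairs
    is_circular = passed_length and passed_overlap and passed_pairs
    circular_seq = circularize(scaffold, overlap) if is_circular else None
    return CircularCall(
        scaffold_id=scaffold.id,
        length=scaffold.length,
        coverage=scaffold.coverage,
        passed_length=passed_length,
        passed_overlap=passed_overlap,
        passed_pairs=passed_pairs,
        overlap=overlap,
        n_junction_pairs=n_junction_pairs,
        is_circular=is_circular,
        circular_seq=circular_seq,
    )


def detect_all(
    scaffolds: Sequence[Scaffold],
    alignments: Sequence[PairedAlignment],
    params: DetectionParams | None = None,
) -> list[CircularCall]:
    """Run the full three-criterion detector over a scaffold set.

    ``alignments`` may cover all scaffolds; pairs are grouped by
    ``scaffold_id``.  Output order follows input scaffold order.
    """
    params = params or DetectionParams()
    by_scaffold: dict[str, list[PairedAlignment]] = {}
    for pair in alignments:
        by_scaffold.setdefault(pair.scaffold_id, []).append(pair)
    calls = []
    for sc in scaffolds:
        overlap = find_end_overlap(sc, params)
        n_pairs = count_junction_pairs(by_scaffold.get(sc.id, []), sc, params)
        calls.append(call_circular(sc, overlap, n_pairs, params))
    return calls


def size_coverage_table(calls: Sequence[CircularCall]) -> list[dict]:
    """Size / coverage rows for the circular plasmids (report plumbing)."""
    return [
        {
            "plasmid_id": c.scaffold_id,
            "circular_length_bp": c.circular_length,
            "coverage": c.coverage,
        }
        for c in calls
        if c.is_circular
    ]
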