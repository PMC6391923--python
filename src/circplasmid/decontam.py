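"""Scaffold-level decontamination filters.

Two removal rules, applied to whole scaffolds (never masked regions):

* 16S rRNA screen — any scaffold with an alignment of more than 200 bp to a
  16S rRNA reference is removed, eliminating chromosomal carry-over.
* Spike-in control screen — any scaffold aligning to one of the spiked
  control plasmids at more than 95% identity over at least 1,000 bp is
  removed, so the controls never inflate the environmental plasmid counts.

The sequence searches themselves (e.g. BLASTN against SILVA or the control
plasmid sequences) are the caller's job; these filters consume the
resulting tabular hit tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqio import PairedAlignment, Scaffold, TabularHit

__all__ = [
    "FilterOutcome",
    "filter_rrna_scaffolds",
    "filter_control_plasmids",
    "fraction_reads_on_removed",
]


@dataclass
class FilterOutcome:
    kept: list[str]
    removed: list[tuple[str, str, TabularHit]]  # (scaffold id, reason, hit)
    reads_on_removed_fraction: Optional[float] = None

    @property
    def removed_ids(self) -> set[str]:
        return {sid for sid, _, _ in self.removed}


def _apply_filter(
    scaffolds: Sequence[Scaffold],
    hits: Sequence[TabularHit],
    reason: str,
    triggers,
) -> FilterOutcome:
    known = {sc.id for sc in scaffolds}
    best: dict[str, TabularHit] = {}
    for hit in hits:
        if hit.query_id not in known:
            raise ValueError(
                f"hit references unknown scaffold {hit.query_id!r}"
            )
        if triggers(hit):
            prev = best.get(hit.query_id)
            # deterministic trigger choice regardless of row order
            if prev is None or (hit.bitscore, hit.aln_len, hit.subject_id) > (
                prev.bitscore, prev.aln_len, prev.subject_id
            ):
                best[hit.query_id] = hit
    kept, removed = [], []
    for sc in scaffolds:
        if sc.id in best:
            removed.append((sc.id, reason, best[sc.id]))
        else:
            kept.append(sc.id)
    return FilterOutcome(kept=kept, removed=removed)


def filter_rrna_scaffolds(
    scaffolds: Sequence[Scaffold],
    rrna_hits: Sequence[TabularHit],
    min_identity_len_bp: int = 200,
    min_pct_identity: float = 0.0,
) -> FilterOutcome:
    """Remove every scaffold with a 16S rRNA hit longer than 200 bp.

    The length threshold is exclusive (a 200-bp hit survives, 201 bp does
    not).  ``min_pct_identity`` is an optional extra floor, off by default:
    the published rule constrains only the alignment length.
    """
    return _apply_filter(
        scaffolds,
        rrna_hits,
        "16S_rRNA",
        lambda h: h.aln_len > min_identity_len_bp
        and h.pct_identity >= min_pct_identity,
    )


def filter_control_plasmids(
    scaffolds: Sequence[Scaffold],
    control_hits: Sequence[TabularHit],
    min_pct_identity: float = 95.0,
    min_aln_len_bp: int = 1000,
) -> FilterOutcome:
    """Remove scaffolds matching a spiked control plasmid.

    Removal requires identity strictly above 95% ("more than 95%") over an
    alignment of at least 1,000 bp (inclusive minimum).
    """
    return _apply_filter(
        scaffolds,
        control_hits,
        "control_plasmid",
        lambda h: h.pct_identity > min_pct_identity
        and h.aln_len >= min_aln_len_bp,
    )


def fraction_reads_on_removed(
    pairs: Sequence[PairedAlignment],
    removed_ids: set[str],
    orphan_placements: Sequence[tuple[str, str]] = (),
) -> float:
    """Fraction of mapped reads on removed scaffolds.

    Each mate counts as one read; ``orphan_placements`` are
    (read_id, scaffold_id) records for mates whose partner did not map,
    counted as single reads.  The denominator is mapped reads only.
    """
    total = 2 * len(pairs) + len(orphan_placements)
    if total == 0:
        raise ValueError("fraction undefined: no mapped reads")
    on_removed = sum(2 for p in pairs if p.scaffold_id in removed_ids)
    on_removed += sum(1 for _, sid in orphan_placements if sid in removed_ids)
    return on_removed / total
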