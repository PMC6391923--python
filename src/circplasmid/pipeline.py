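"""Pipeline orchestration: decontaminate, detect circles, type, report.

Stage order mirrors the study workflow: 16S-scaffold removal, control-
plasmid removal, three-criterion circularity detection on the kept
scaffolds, then optional mobility/MOB/Inc typing.  The report carries the
count identities (in = kept + removed; circular <= kept) plus provenance
(parameters, input checksums) so reruns are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import edlib
import yaml

from . import circdetect, classify, decontam, seqio

logger = logging.getLogger("circplasmid")

REPORT_SCHEMA_VERSION = 1

__all__ = ["RunReport", "run_pipeline", "shared_plasmids"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    schema_version: int
    n_scaffolds_in: int
    n_removed_rrna: int
    n_removed_control: int
    n_kept: int
    n_circular: int
    reads_on_removed_fraction: Optional[float]
    size_coverage: list[dict]
    type_summary: Optional[dict]
    params: dict
    input_checksums: dict

    def to_json(self, path: str | os.PathLike) -> None:
        def default(obj):
            if isinstance(obj, Fraction):
                return float(obj)
            raise TypeError(type(obj))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=default)
            fh.write("\n")


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: dict, key: str, stage: str) -> str:
    if key not in config or config[key] is None:
        raise PipelineError(stage, f"config is missing required input {key!r}")
    return config[key]


def run_pipeline(config: dict | str | os.PathLike) -> RunReport:
    """Execute decontam(16S) -> decontam(controls) -> detect -> classify.

    ``config`` is a mapping (or path to a YAML file) with keys:
    ``scaffolds`` (FASTA), ``alignments`` (path), ``alignment_dialect``
    (``sam-subset`` | ``internal-tsv``), ``rrna_hits`` and ``control_hits``
    (12-column TSV), optional ``marker_profiles`` (TSV), optional ``params``
    (DetectionParams field overrides) and optional ``outdir`` for artifacts.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    scaffolds_path = _require(config, "scaffolds", "input")
    alignments_path = _require(config, "alignments", "input")
    dialect = config.get("alignment_dialect", "internal-tsv")
    rrna_path = _require(config, "rrna_hits", "input")
    control_path = _require(config, "control_hits", "input")
    params = seqio.DetectionParams(**config.get("params", {}))
    outdir = Path(config["outdir"]) if config.get("outdir") else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    checksums = {
        name: _sha256(path)
        for name, path in (
            ("scaffolds", scaffolds_path),
            ("alignments", alignments_path),
            ("rrna_hits", rrna_path),
            ("control_hits", control_path),
        )
    }

    try:
        scaffolds = seqio.read_fasta(scaffolds_path)
        parse_result = seqio.parse_paired_alignments(alignments_path, dialect)
        rrna_hits = seqio.parse_tabular_hits(rrna_path)
        control_hits = seqio.parse_tabular_hits(control_path)
    except seqio.FormatError as exc:
        raise PipelineError("input", str(exc)) from exc
    logger.info(
        "loaded %d scaffolds, %d read pairs", len(scaffolds),
        len(parse_result.pairs),
    )

    # mean per-base depth from the mapped pairs (FASTA carries no coverage)
    depth_sum: dict[str, int] = {}
    for p in parse_result.pairs:
        depth_sum[p.scaffold_id] = depth_sum.get(p.scaffold_id, 0) + (
            p.m1_end - p.m1_start
        ) + (p.m2_end - p.m2_start)
    scaffolds = [
        dataclasses.replace(
            sc, coverage=round(depth_sum.get(sc.id, 0) / sc.length, 2)
        )
        if sc.coverage is None
        else sc
        for sc in scaffolds
    ]

    rrna_outcome = decontam.filter_rrna_scaffolds(scaffolds, rrna_hits)
    after_rrna = [sc for sc in scaffolds if sc.id in set(rrna_outcome.kept)]
    control_outcome = decontam.filter_control_plasmids(after_rrna, [
        h for h in control_hits if h.query_id not in rrna_outcome.removed_ids
    ])
    kept = [sc for sc in after_rrna if sc.id in set(control_outcome.kept)]
    removed_ids = rrna_outcome.removed_ids | control_outcome.removed_ids
    logger.info(
        "decontam removed %d (16S) + %d (control) of %d scaffolds",
        len(rrna_outcome.removed), len(control_outcome.removed), len(scaffolds),
    )

    frac = None
    if parse_result.pairs:
        frac = decontam.fraction_reads_on_removed(
            parse_result.pairs, removed_ids
        )

    kept_ids = {sc.id for sc in kept}
    kept_pairs = [p for p in parse_result.pairs if p.scaffold_id in kept_ids]
    calls = circdetect.detect_all(kept, kept_pairs, params)
    n_circular = sum(c.is_circular for c in calls)
    logger.info("detected %d circular plasmids among %d kept scaffolds",
                n_circular, len(kept))

    type_summary = None
    if config.get("marker_profiles"):
        profiles = classify.load_marker_profiles(config["marker_profiles"])
        circ_ids = {c.scaffold_id for c in calls if c.is_circular}
        type_calls = classify.classify_all(
            [p for p in profiles if p.plasmid_id in circ_ids]
        )
        sizes = {
            c.scaffold_id: c.circular_length
            for c in calls
            if c.is_circular
        }
        type_summary = classify.summarize_types(type_calls, sizes)

    report = RunReport(
        schema_version=REPORT_SCHEMA_VERSION,
        n_scaffolds_in=len(scaffolds),
        n_removed_rrna=len(rrna_outcome.removed),
        n_removed_control=len(control_outcome.removed),
        n_kept=len(kept),
        n_circular=n_circular,
        reads_on_removed_fraction=frac,
        size_coverage=circdetect.size_coverage_table(calls),
        type_summary=type_summary,
        params=dataclasses.asdict(params),
        input_checksums=checksums,
    )
    assert report.n_scaffolds_in == report.n_kept + report.n_removed_rrna + report.n_removed_control
    assert report.n_circular <= report.n_kept

    if outdir:
        _write_artifacts(outdir, kept, calls, report)
    return report


def _write_artifacts(outdir: Path, kept, calls, report: RunReport) -> None:
    seqio.write_fasta(kept, outdir / "kept_scaffolds.fasta")
    circulars = [
        seqio.Scaffold(id=c.scaffold_id, seq=c.circular_seq, coverage=c.coverage)
        for c in calls
        if c.is_circular
    ]
    seqio.write_fasta(circulars, outdir / "circular_plasmids.fasta")
    with open(outdir / "calls.tsv", "w") as fh:
        fh.write(
            "scaffold_id\tlength\tcoverage\tpassed_length\tpassed_overlap\t"
            "overlap_len\toverlap_evalue\tn_junction_pairs\tis_circular\t"
            "circular_len\n"
        )
        for c in calls:
            ov_len = c.overlap.length if c.overlap else ""
            ov_e = f"{c.overlap.evalue:.3g}" if c.overlap else ""
            fh.write(
                f"{c.scaffold_id}\t{c.length}\t{c.coverage if c.coverage is not None else ''}\t"
                f"{c.passed_length}\t{c.passed_overlap}\t{ov_len}\t{ov_e}\t"
                f"{c.n_junction_pairs}\t{c.is_circular}\t"
                f"{c.circular_length if c.circular_length is not None else ''}\n"
            )
    report.to_json(outdir / "report.json")


# ---------------------------------------------------------------------------
# Cross-sample shared-plasmid comparison
# ---------------------------------------------------------------------------

def _rotation_invariant_match(query: str, target: str) -> tuple[float, float]:
    """(percent identity, percent query coverage) of query vs circular target.

    The query is aligned as an infix of the doubled target so any rotation
    of the underlying circle is found.  Identity is (|q| - edit distance) /
    |q|; a poor containment surfaces as low identity.
    """
    if len(query) > 2 * len(target):
        return 0.0, 0.0
    res = edlib.align(query, target + target, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return 0.0, 0.0
    identity = 100.0 * max(0, len(query) - dist) / len(query)
    return identity, 100.0


def shared_plasmids(
    circulars_a: Sequence[seqio.Scaffold],
    circulars_b: Sequence[seqio.Scaffold],
    min_pct_identity: float = 99.8,
    min_query_coverage: float = 93.6,
) -> list[tuple[str, str]]:
    """Plasmids shared between two samples, rotation-invariantly.

    A pair matches when it is a reciprocal best hit with identity strictly
    above ``min_pct_identity`` and query coverage strictly above
    ``min_query_coverage`` (both directions).  Returns (id_a, id_b) pairs.
    """
    def best_partner(query, pool):
        scored = []
        for cand in pool:
            ident, cov = _rotation_invariant_match(query.seq, cand.seq)
            if ident > min_pct_identity and cov > min_query_coverage:
                scored.append((ident, cov, cand.id))
        if not scored:
            return None
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        return scored[0][2]

    forward = {a.id: best_partner(a, circulars_b) for a in circulars_a}
    backward = {b.id: best_partner(b, circulars_a) for b in circulars_b}
    matches = [
        (aid, bid)
        for aid, bid in forward.items()
        if bid is not None and backward.get(bid) == aid
    ]
    return sorted(matches)
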