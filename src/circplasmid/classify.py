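"""Rule-based plasmid typing: mobility class, MOB relaxase family, Inc group.

Mobility follows the operational transfer-gene scheme: a plasmid carrying a
relaxase together with a type IV secretion system (T4SS) is self-
transmissible (conjugative); a relaxase without a T4SS marks a plasmid that
can hitch-hike on another element's machinery (mobilizable); a plasmid with
neither is nonmobilizable.  The type IV coupling protein (T4CP) and the
transfer/replication origins (oriT, oriV) are carried in the profile for
reporting but never change the class — origins in particular are rarely
detectable by homology.

MOB typing assigns the family of the best-scoring relaxase hit among the
seven recognized families; incompatibility (Inc) grouping assigns the best-
scoring replicon-typing scheme label.  Marker detection itself (HMM or
reference searches) is upstream; this module consumes its hit tables.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

__all__ = [
    "MOB_FAMILIES",
    "MOBILITY_CLASSES",
    "MarkerProfile",
    "PlasmidTypeCall",
    "classify_mobility",
    "assign_mob_type",
    "assign_inc_group",
    "summarize_types",
    "load_marker_profiles",
]

# Fixed priority order for tie-breaking; also the canonical display order.
MOB_FAMILIES = ("MOBF", "MOBP", "MOBQ", "MOBC", "MOBV", "MOBB", "MOBT")

MOBILITY_CLASSES = ("conjugative", "mobilizable", "nonmobilizable")

# Canonical order for Inc scheme labels; equal-score ties across schemes are
# reported as a combined "A or B" label in this order.
INC_LABELS = (
    "IncA/C cgPMLST",
    "IncA/C PMLST",
    "IncF RST",
    "IncHI1 MLST",
    "IncHI2 DLST",
    "IncI1 MLST",
    "IncN MLST",
)

UNTYPED = "untyped"

DEFAULT_MIN_BITSCORE = 50.0

DEFAULT_SIZE_BINS_BP = (0, 10_000, 50_000, 100_000, float("inf"))
DEFAULT_SIZE_BIN_LABELS = ("<10 kb", "10-50 kb", "50-100 kb", ">100 kb")


@dataclass(frozen=True)
class MarkerProfile:
    plasmid_id: str
    relaxase_hits: tuple[tuple[str, float], ...] = ()   # (MOB family, bitscore)
    has_t4cp: bool = False
    has_t4ss: bool = False
    has_orit: bool = False
    has_oriv: bool = False
    inc_hits: tuple[tuple[str, float], ...] = ()        # (Inc label, bitscore)

    def __post_init__(self) -> None:
        for fam, score in self.relaxase_hits:
            if fam not in MOB_FAMILIES:
                raise ValueError(
                    f"{self.plasmid_id!r}: unknown MOB family {fam!r}"
                )
            if score < 0:
                raise ValueError(f"{self.plasmid_id!r}: negative bitscore")
        for _, score in self.inc_hits:
            if score < 0:
                raise ValueError(f"{self.plasmid_id!r}: negative bitscore")


@dataclass(frozen=True)
class PlasmidTypeCall:
    plasmid_id: str
    mobility: str
    mob_type: str
    inc_group: str


def classify_mobility(profile: MarkerProfile) -> str:
    """Mobility class from relaxase / T4SS presence (T4CP is informational)."""
    has_relaxase = bool(profile.relaxase_hits)
    if has_relaxase and profile.has_t4ss:
        return "conjugative"
    if has_relaxase:
        return "mobilizable"
    return "nonmobilizable"


def assign_mob_type(profile: MarkerProfile) -> str:
    """MOB family of the highest-bitscore relaxase hit.

    Ties break by the fixed family order MOBF > MOBP > MOBQ > MOBC > MOBV >
    MOBB > MOBT so repeated runs on shuffled hit lists agree.
    """
    if not profile.relaxase_hits:
        return UNTYPED
    best = max(
        profile.relaxase_hits,
        key=lambda h: (h[1], -MOB_FAMILIES.index(h[0])),
    )
    return best[0]


def _inc_rank(label: str) -> tuple[int, str]:
    try:
        return (INC_LABELS.index(label), label)
    except ValueError:
        return (len(INC_LABELS), label)


def assign_inc_group(profile: MarkerProfile) -> str:
    """Inc label of the highest-bitscore replicon-scheme hit.

    When two schemes tie at the top score the call is ambiguous between
    them and the combined label (e.g. "IncA/C cgPMLST or IncA/C PMLST")
    is reported.
    """
    if not profile.inc_hits:
        return UNTYPED
    top = max(score for _, score in profile.inc_hits)
    winners = sorted(
        {label for label, score in profile.inc_hits if score == top},
        key=_inc_rank,
    )
    return " or ".join(winners)


def classify_all(profiles: Sequence[MarkerProfile]) -> list[PlasmidTypeCall]:
    return [
        PlasmidTypeCall(
            plasmid_id=p.plasmid_id,
            mobility=classify_mobility(p),
            mob_type=assign_mob_type(p),
            inc_group=assign_inc_group(p),
        )
        for p in profiles
    ]


def summarize_types(
    calls: Sequence[PlasmidTypeCall],
    sizes: dict[str, int],
    size_bins_bp: Sequence[float] = DEFAULT_SIZE_BINS_BP,
    size_bin_labels: Sequence[str] = DEFAULT_SIZE_BIN_LABELS,
) -> dict:
    """Cohort summary: mobility fractions, MOB counts, MOB-by-size table.

    Mobility fractions are exact rationals over the call count and sum to 1
    whenever any calls exist.  ``sizes`` maps plasmid id to circular length
    in bp; every call must have a size.
    """
    if len(size_bin_labels) != len(size_bins_bp) - 1:
        raise ValueError("size bin labels must match bin edges")
    missing = [c.plasmid_id for c in calls if c.plasmid_id not in sizes]
    if missing:
        raise ValueError(f"no size for plasmid ids {missing}")

    n = len(calls)
    mobility_counts = {m: 0 for m in MOBILITY_CLASSES}
    mob_counts: dict[str, int] = {}
    mob_by_size = {
        label: {fam: 0 for fam in (*MOB_FAMILIES, UNTYPED)}
        for label in size_bin_labels
    }
    for call in calls:
        mobility_counts[call.mobility] += 1
        mob_counts[call.mob_type] = mob_counts.get(call.mob_type, 0) + 1
        size = sizes[call.plasmid_id]
        for lo, hi, label in zip(size_bins_bp, size_bins_bp[1:], size_bin_labels):
            if lo <= size < hi:
                mob_by_size[label][call.mob_type] += 1
                break
    mobility_fractions = {
        m: (Fraction(c, n) if n else Fraction(0)) for m, c in mobility_counts.items()
    }
    return {
        "n_plasmids": n,
        "mobility_counts": mobility_counts,
        "mobility_fractions": mobility_fractions,
        "mob_counts": mob_counts,
        "mob_by_size": mob_by_size,
    }


def load_marker_profiles(
    path: str | os.PathLike, min_bitscore: float = DEFAULT_MIN_BITSCORE
) -> list[MarkerProfile]:
    """Read marker hits from TSV and build per-plasmid profiles.

    Columns: plasmid_id, marker_class, subject_id, bitscore, family_or_label.
    marker_class is one of relaxase, t4ss, t4cp, orit, oriv, inc.  Hits below
    ``min_bitscore`` are ignored (presence needs a credible hit; the floor is
    configurable policy, not a published threshold).
    """
    rows: dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        expected = {"plasmid_id", "marker_class", "subject_id", "bitscore",
                    "family_or_label"}
        if set(reader.fieldnames or ()) != expected:
            raise ValueError(f"{path}: expected columns {sorted(expected)}")
        for rec in reader:
            score = float(rec["bitscore"])
            if score < min_bitscore:
                continue
            entry = rows.setdefault(
                rec["plasmid_id"],
                {"relaxase": [], "inc": [], "t4ss": False, "t4cp": False,
                 "orit": False, "oriv": False},
            )
            cls = rec["marker_class"].lower()
            if cls == "relaxase":
                entry["relaxase"].append((rec["family_or_label"], score))
            elif cls == "inc":
                entry["inc"].append((rec["family_or_label"], score))
            elif cls in ("t4ss", "t4cp", "orit", "oriv"):
                entry[cls] = True
            else:
                raise ValueError(f"{path}: unknown marker_class {cls!r}")
    return [
        MarkerProfile(
            plasmid_id=pid,
            relaxase_hits=tuple(e["relaxase"]),
            has_t4cp=e["t4cp"],
            has_t4ss=e["t4ss"],
            has_orit=e["orit"],
            has_oriv=e["oriv"],
            inc_hits=tuple(e["inc"]),
        )
        for pid, e in rows.items()
    ]
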