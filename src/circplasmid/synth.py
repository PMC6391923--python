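"""Synthetic plasmidome communities with ground truth.

Emulates the inputs the detection pipeline consumes, with a truth table for
every emitted scaffold and read pair:

* circular plasmids, emitted as linear scaffolds carrying an exact terminal
  direct repeat (the assembler's signature of an underlying circle);
* linear chromosomal decoys and 16S-carrying decoys (the decontamination
  targets);
* spiked control plasmids, defaulting to the 5 / 48 / 202 kb replicons of
  the three-strain model system, at elevated depth;
* FR paired-end reads drawn from the circular template, so junction-spanning
  fragments arise at the analytic rate (insert - 1) / L;
* a naive exact-k-mer mapper so the full pipeline runs with no external
  aligner or databases.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .classify import MarkerProfile
from .seqio import PairedAlignment, Scaffold, TabularHit, revcomp

__all__ = [
    "PlasmidSpec",
    "DecoySpec",
    "RrnaDecoySpec",
    "ControlSpec",
    "CommunitySpec",
    "ReadPair",
    "TruthTable",
    "Community",
    "random_dna",
    "generate_community",
    "simulate_read_pairs",
    "map_reads_naive",
    "truth_hit_tables",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


@dataclass(frozen=True)
class PlasmidSpec:
    length: int                  # circular length, bp
    depth: float = 20.0          # nominal read coverage
    overlap_len: int = 100       # terminal direct repeat planted on the scaffold
    overlap_mismatches: int = 0  # mutations in the suffix copy (E-value path)
    profile: Optional[MarkerProfile] = None


@dataclass(frozen=True)
class DecoySpec:
    length: int
    depth: float = 20.0


@dataclass(frozen=True)
class RrnaDecoySpec:
    length: int
    rrna_len: int = 300          # planted 16S fragment length (drives the hit table)
    depth: float = 20.0


@dataclass(frozen=True)
class ControlSpec:
    length: int
    depth: float = 100.0         # spiked controls dominate, as designed


DEFAULT_CONTROLS = (
    ControlSpec(length=5_000),
    ControlSpec(length=48_000),
    ControlSpec(length=202_000),
)


@dataclass(frozen=True)
class CommunitySpec:
    plasmids: tuple[PlasmidSpec, ...] = ()
    chromosomal_decoys: tuple[DecoySpec, ...] = ()
    rrna_decoys: tuple[RrnaDecoySpec, ...] = ()
    controls: tuple[ControlSpec, ...] = DEFAULT_CONTROLS
    read_len: int = 150
    insert_mean: float = 450.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for group in (self.plasmids, self.chromosomal_decoys,
                      self.rrna_decoys, self.controls):
            for member in group:
                if member.length <= 0 or member.depth <= 0:
                    raise ValueError("lengths and depths must be positive")
        if self.insert_mean <= self.read_len:
            raise ValueError("insert_mean must exceed read_len")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1: str
    r2: str


@dataclass(frozen=True)
class PairTruth:
    read_id: str
    template_id: str
    frag_start: int       # on the template (circular coords for circles)
    insert: int
    junction_spanning: bool


@dataclass(frozen=True)
class ScaffoldTruth:
    scaffold_id: str
    origin: str           # plasmid | chromosome | rrna_decoy | control
    is_circular: bool
    overlap_len: int      # planted terminal repeat length (0 for linear)
    template_len: int     # circular length for circles, else scaffold length
    rrna_len: int = 0


@dataclass
class TruthTable:
    scaffolds: dict[str, ScaffoldTruth] = field(default_factory=dict)
    pairs: list[PairTruth] = field(default_factory=list)


@dataclass
class Community:
    scaffolds: list[Scaffold]
    reads: list[ReadPair]
    truth: TruthTable
    spec: CommunitySpec


def plant_terminal_repeat(
    circle: str, overlap_len: int, mismatches: int, rng: np.random.Generator
) -> str:
    """Linearize a circle as scaffold = circle + first overlap_len bases.

    ``mismatches`` substitutions, if any, go into the suffix copy at distinct
    interior positions so the planted repeat length is unambiguous.
    """
    if overlap_len >= len(circle):
        raise ValueError("terminal repeat must be shorter than the circle")
    suffix = list(circle[:overlap_len])
    if mismatches:
        positions = rng.choice(overlap_len, size=mismatches, replace=False)
        for pos in positions:
            current = suffix[pos]
            choices = [b for b in "ACGT" if b != current]
            suffix[pos] = choices[rng.integers(len(choices))]
    return circle + "".join(suffix)


def simulate_read_pairs(
    template: str,
    circular: bool,
    n_pairs: int,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    rng: np.random.Generator,
    template_id: str = "template",
) -> tuple[list[ReadPair], list[PairTruth]]:
    """FR read pairs from fragments uniform on the template.

    Circular templates wrap across the origin, producing junction-spanning
    fragments at expected rate (insert - 1) / L.  Inserts are normal,
    rounded, clamped to [read_len, L].  Errors are substitutions.
    """
    L = len(template)
    if n_pairs == 0:
        return [], []
    if not circular and insert_mean >= L:
        raise ValueError("insert_mean must be below linear template length")
    doubled = template + template if circular else template
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    inserts = np.clip(inserts, read_len, L)
    if circular:
        starts = rng.integers(0, L, size=n_pairs)
    else:
        starts = np.floor(rng.random(n_pairs) * (L - inserts + 1)).astype(int)
    reads: list[ReadPair] = []
    truth: list[PairTruth] = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag = doubled[s : s + ins]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        if error_rate > 0:
            r1 = _mutate(r1, error_rate, rng)
            r2 = _mutate(r2, error_rate, rng)
        rid = f"{template_id}_p{i}"
        reads.append(ReadPair(rid, r1, r2))
        truth.append(
            PairTruth(
                read_id=rid,
                template_id=template_id,
                frag_start=s,
                insert=ins,
                junction_spanning=bool(circular and s + ins > L),
            )
        )
    return reads, truth


def _mutate(read: str, error_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for pos in hits:
        current = arr[pos]
        choices = [b for b in BASES if b != current]
        arr[pos] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _n_pairs(depth: float, template_len: int, read_len: int) -> int:
    return max(1, round(depth * template_len / (2 * read_len)))


def generate_community(spec: CommunitySpec) -> Community:
    """Materialize a community: scaffolds, reads, and the truth table."""
    rng = np.random.default_rng(spec.seed)
    scaffolds: list[Scaffold] = []
    reads: list[ReadPair] = []
    truth = TruthTable()

    def add_member(
        sid: str, origin: str, template: str, circular: bool,
        depth: float, overlap_len: int, rrna_len: int = 0,
        scaffold_seq: Optional[str] = None,
    ) -> None:
        seq = scaffold_seq if scaffold_seq is not None else template
        scaffolds.append(Scaffold(id=sid, seq=seq, coverage=depth))
        truth.scaffolds[sid] = ScaffoldTruth(
            scaffold_id=sid, origin=origin, is_circular=circular,
            overlap_len=overlap_len, template_len=len(template),
            rrna_len=rrna_len,
        )
        pairs, pair_truth = simulate_read_pairs(
            template, circular,
            _n_pairs(depth, len(template), spec.read_len),
            spec.read_len, spec.insert_mean, spec.insert_sd,
            spec.error_rate, rng, template_id=sid,
        )
        reads.extend(pairs)
        truth.pairs.extend(pair_truth)

    for i, pl in enumerate(spec.plasmids):
        circle = random_dna(pl.length, rng)
        scaffold_seq = plant_terminal_repeat(
            circle, pl.overlap_len, pl.overlap_mismatches, rng
        )
        add_member(
            f"plasmid_{i}", "plasmid", circle, True, pl.depth,
            pl.overlap_len, scaffold_seq=scaffold_seq,
        )
    for i, dc in enumerate(spec.chromosomal_decoys):
        add_member(
            f"chrom_decoy_{i}", "chromosome", random_dna(dc.length, rng),
            False, dc.depth, 0,
        )
    for i, rd in enumerate(spec.rrna_decoys):
        add_member(
            f"rrna_decoy_{i}", "rrna_decoy", random_dna(rd.length, rng),
            False, rd.depth, 0, rrna_len=rd.rrna_len,
        )
    for i, ct in enumerate(spec.controls):
        circle = random_dna(ct.length, rng)
        overlap = 100
        scaffold_seq = plant_terminal_repeat(circle, overlap, 0, rng)
        add_member(
            f"control_{i}", "control", circle, True, ct.depth,
            overlap, scaffold_seq=scaffold_seq,
        )
    return Community(scaffolds=scaffolds, reads=reads, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# Naive mapper — exact k-mer seed, ungapped verification
# ---------------------------------------------------------------------------

@dataclass
class MapStats:
    mapped_pairs: int = 0
    unmapped_reads: int = 0
    ambiguous_reads: int = 0
    orphan_pairs: int = 0
    cross_scaffold_pairs: int = 0
    orphan_placements: list[tuple[str, str]] = field(default_factory=list)


def _best_placement(
    read: str,
    index: dict[str, list[tuple[int, int]]],
    seqs: list[str],
    k: int,
    max_mismatches: int,
) -> Optional[tuple[int, int, str, int]]:
    """Best unique (scaffold_idx, start, strand, mismatches) or None."""
    candidates: dict[tuple[int, int, str], int] = {}
    exact_found = False
    for oriented, strand in ((read, "+"), (revcomp(read), "-")):
        if exact_found:
            break
        offsets = range(0, len(oriented) - k + 1, k)
        for off in offsets:
            for sc_idx, pos in index.get(oriented[off : off + k], ()):
                start = pos - off
                key = (sc_idx, start, strand)
                if key in candidates or start < 0:
                    continue
                target = seqs[sc_idx][start : start + len(oriented)]
                if len(target) < len(oriented):
                    continue
                if target == oriented:
                    mm = 0
                    exact_found = True
                else:
                    mm = sum(a != b for a, b in zip(oriented, target))
                    if mm > max_mismatches:
                        continue
                candidates[key] = mm
            # one seed offset already enumerates every exact placement of
            # this orientation (an exact placement matches all its k-mers)
            if exact_found:
                break
    if not candidates:
        return None
    best_mm = min(candidates.values())
    winners = [key for key, mm in candidates.items() if mm == best_mm]
    if len(winners) > 1:
        return "ambiguous"  # type: ignore[return-value]
    (sc_idx, start, strand) = winners[0]
    return sc_idx, start, strand, best_mm


def map_reads_naive(
    reads: Sequence[ReadPair],
    scaffolds: Sequence[Scaffold],
    k: int = 31,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[PairedAlignment], MapStats]:
    """Map read pairs by exact k-mer seeding and ungapped extension.

    Intended for synthetic, error-free or low-error reads only.  A read with
    several equally good placements is dropped as ambiguous; a pair whose
    mates land on different scaffolds is tallied, not returned.
    """
    if reads and k > min(len(r.r1) for r in reads):
        raise ValueError("k exceeds read length")
    seqs = [sc.seq for sc in scaffolds]
    index: dict[str, list[tuple[int, int]]] = {}
    for sc_idx, seq in enumerate(seqs):
        for pos in range(0, len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((sc_idx, pos))

    stats = MapStats()
    pairs: list[PairedAlignment] = []
    for rp in reads:
        placements = []
        for mate in (rp.r1, rp.r2):
            max_mm = int(max_mismatch_frac * len(mate))
            hit = _best_placement(mate, index, seqs, k, max_mm)
            if hit is None:
                stats.unmapped_reads += 1
                placements.append(None)
            elif hit == "ambiguous":
                stats.ambiguous_reads += 1
                placements.append(None)
            else:
                placements.append(hit)
        p1, p2 = placements
        if p1 is None and p2 is None:
            continue
        if p1 is None or p2 is None:
            stats.orphan_pairs += 1
            placed = p1 or p2
            stats.orphan_placements.append(
                (rp.read_id, scaffolds[placed[0]].id)
            )
            continue
        if p1[0] != p2[0]:
            stats.cross_scaffold_pairs += 1
            continue
        sc = scaffolds[p1[0]]
        pairs.append(
            PairedAlignment(
                read_id=rp.read_id,
                scaffold_id=sc.id,
                m1_start=p1[1], m1_end=p1[1] + len(rp.r1), m1_strand=p1[2],
                m2_start=p2[1], m2_end=p2[1] + len(rp.r2), m2_strand=p2[2],
            )
        )
        stats.mapped_pairs += 1
    return pairs, stats


def truth_hit_tables(
    community: Community,
) -> tuple[list[TabularHit], list[TabularHit]]:
    """Hit tables the decontamination screens would produce, from truth.

    16S hits: one per rrna decoy, alignment length equal to the planted
    fragment.  Control hits: one per control scaffold, full-length at 100%
    identity against its spiked reference.
    """
    rrna_hits, control_hits = [], []
    for sid, st in community.truth.scaffolds.items():
        if st.origin == "rrna_decoy":
            rrna_hits.append(
                TabularHit(sid, "SILVA_16S_ref", 98.0, st.rrna_len, 0, 0,
                           1, st.rrna_len, 1, st.rrna_len, 1e-50,
                           2.0 * st.rrna_len)
            )
        elif st.origin == "control":
            aln = st.template_len
            control_hits.append(
                TabularHit(sid, f"spike_{st.template_len}bp", 100.0, aln,
                           0, 0, 1, aln, 1, aln, 0.0, 2.0 * aln)
            )
    return rrna_hits, control_hits
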