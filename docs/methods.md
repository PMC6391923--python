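# Methods

## Model and assumptions

The detector treats an assembled scaffold as a candidate linearization of a
circular plasmid. Two observable consequences of circularity are used, and
only these: (a) assemblers extending past the replication origin emit the
start of the circle a second time, leaving a terminal direct repeat on the
scaffold; (b) sequencing fragments that straddle the origin produce read
pairs whose mates map near opposite ends of the linearized scaffold, facing
outward in linear coordinates. Neither signature alone is reliable — short
terminal repeats arise by chance and chimeric pairs mimic junction
evidence — so the call is the conjunction of three criteria (length,
end-overlap, junction pairs). The method therefore only ever *confirms*
circularity; a circular plasmid assembled without a terminal repeat, or
sequenced too shallowly to leave two junction pairs, is reported linear.
This is a deliberate precision-over-recall trade.

## Detection parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_scaffold_bp` | 2000 (exclusive) | bp | criterion (i); 2,000 bp fails |
| `min_overlap_bp` | 34 (exclusive) | bp | criterion (ii) alignment length; 34 bp fails |
| `max_evalue` | 1e−5 | — | criterion (ii) significance ceiling |
| `search_window_bp` | 1000 | bp | terminal window searched for the repeat |
| `end_window_bp` | 500 (inclusive) | bp | criterion (iii) terminal windows |
| `min_junction_pairs` | 2 (inclusive) | pairs | criterion (iii) |
| `ka_lambda`, `ka_k` | 1.28, 0.46 | — | ungapped Karlin–Altschul constants |
| match / mismatch / gap | +1 / −2 / −2 | score | local-alignment scoring |

The threshold strictness follows the wording of the criteria literally:
"> 2 kb" and "> 34 bp" are exclusive, "at least two" and "a maximum of
500 bp" inclusive. An E-value that must *exceed* 10⁻⁵ would reward weak
homology, so the implemented reading is E ≤ 10⁻⁵. The E-value is computed
from the raw local-alignment score in the ungapped Karlin–Altschul form
with the two window lengths as m and n; λ and K are standard nucleotide
search constants for +1/−2 scoring and are configuration values, as the
criteria name only the E-value ceiling. `find_end_overlap` reports no
overlap when the best alignment misses that ceiling — absence is a value.

The 1,000-bp search window (truncated to ⌊L/2⌋ on short scaffolds, so the
two windows never overlap) is a design choice: assembler-induced terminal
repeats are short relative to it, and it bounds alignment cost at
10⁶ cells per scaffold. Ambiguity among co-optimal overlaps resolves by
highest score, then the aligner's deterministic enumeration order, so
repeated runs agree.

"A maximum of 500 bp from the end" is read in its strictest unambiguous
form: the mate's whole interval must lie inside the terminal window. The
orientation requirement (start-proximal mate on −, end-proximal on +) is
what an FR fragment spanning the junction produces and screens out
chimeric pairs; a permissive mode (`require_junction_orientation=False`)
implements the looser "opposite ends" reading.

Circularization removes the bases covered by the suffix copy of the repeat,
so the circular length equals scaffold length minus the suffix span; the
doubled result always contains the original scaffold as a substring
(rotation equivalence), which the tests exercise as a property.

## Decontamination

Both filters operate on externally produced 12-column tabular hit tables
and remove whole scaffolds, never masked regions, because a scaffold
carrying any 16S rRNA sequence is chromosomal contamination in a plasmid
preparation regardless of what else it carries. "200-bp identity" is
implemented as alignment length > 200 bp with no identity-percentage floor
(the rule constrains only length; an optional floor exists). The control
filter requires identity > 95% *and* alignment ≥ 1,000 bp jointly. Filters
are order-independent and commute; the reads-on-removed fraction counts
each mapped mate individually (plus orphan placements) over mapped reads
only — the denominator choice is recorded here because the alternative
(all reads, mapped or not) is defensible but unverifiable from a hit
table.

## Typing rules

Mobility is a total function of two booleans: relaxase presence and T4SS
presence. T4CP, oriT and oriV ride along in the profile for reporting but
never alter the class; origins in particular are rarely detectable by
homology, so conditioning on them would silently demote real conjugative
plasmids. MOB type is the family of the best-scoring relaxase hit, ties
broken by the fixed order MOBF > MOBP > MOBQ > MOBC > MOBV > MOBB > MOBT
(determinism; no biological ranking is implied). Inc group is the
best-scoring scheme label; an exact score tie across schemes is reported
as the combined "A or B" label rather than resolved arbitrarily. Marker
presence requires bitscore ≥ 50 when profiles are loaded from TSV — a
package policy, not a published threshold, and configurable. Mobility
fractions are exact rationals over the call count, so they sum to 1
identically.

## Synthetic communities

The generator emulates the inputs the pipeline consumes: circular plasmids
(2–2,000 kb supported) linearized with an exact terminal direct repeat,
linear chromosomal decoys, 16S-carrying decoys, and spiked control
replicons defaulting to 5, 48 and 202 kb at elevated depth, mirroring a
three-strain control mixture. Reads are FR pairs with normal insert length
(clamped to [read length, template length]) drawn uniformly from the
*circular* template, so junction-spanning fragments arise at the analytic
rate (insert − 1)/L; errors are substitutions only, since the detector
consumes alignments, not base qualities. Read pairs per member are
depth·L/(2·read_len).

Defaults are 2×150 bp reads with insert 450 ± 50 bp. The read length
matters: with 2×300 reads at insert 450 the mates overlap and *cannot*
both lie wholly inside opposite 500-bp terminal windows, making criterion
(iii) structurally unsatisfiable under the strict window reading. At
2×150/450 the countable junction yield is ≈ 0.8×depth per circular
scaffold independent of plasmid size, so ≥ 20× depth leaves the two-pair
requirement with enormous margin.

The naive mapper (exact 31-mer seed, ungapped verification, best unique
placement, ambiguous and unmapped reads tallied) is intended solely for
synthetic reads; reads wrapping the origin farther than the planted repeat
are unmappable and dropped, which slightly depresses junction counts and
is accounted for in the truth-derived test oracles.

What passing tests on these communities shows — and does not show: the
decision logic, coordinate handling and thresholds are exact, and the
pipeline recovers planted truth perfectly under uniform composition,
error-free reads and exact repeats. Real assemblies add repeat-induced
misassembly, coverage bias from multiple-displacement amplification,
chimeric pairs and degenerate terminal repeats; none of these are modeled,
so field performance is bounded by assembly and mapping quality, not by
this implementation.

## Cross-sample comparison

`shared_plasmids` matches circular plasmids between two samples by
reciprocal best hit with identity > 99.8% and query coverage > 93.6%
(both strict). Rotation invariance comes from aligning each query against
the doubled partner (infix edit-distance alignment); identity is
(|q| − edit distance)/|q|, and query coverage is the aligned query span
over query length, which for infix alignment is 100% — a poor containment
therefore surfaces as low identity. Reciprocal-best was chosen over
one-directional matching to keep the relation symmetric.

## Problem sizes and numerical notes

The bundled validation communities use 20 circular plasmids of 3–250 kb
(including a 202-kb control-scale replicon), 10 linear decoys and 3 spiked
controls at 20–40× error-free coverage across five seeds — large enough
that every criterion is exercised far from its boundary, small enough to
run in about a minute per seed. Boundary placement is tested by dedicated
1-bp (or 0.5-percentage-point) sweeps instead. All randomness flows
through explicitly seeded NumPy generators; the detector itself is
seed-free and deterministic, including every tie-break.
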