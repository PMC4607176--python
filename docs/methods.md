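# Methods

This note records the models behind each patrrkit component, the defaults
that matter, and the choices made where the design was genuinely open.

## Coordinates and sequence handling

All user-facing coordinates are 1-based inclusive with strand, the idiom
used for genomic spans like "positions 911–1964"; BED output converts to
0-based half-open, with the score column carrying A+T% × 10. FASTA input is
uppercased, `U` is mapped to `T`, and any other IUPAC ambiguity code is
mapped to `N` with a logged warning. `N` counts toward length but never
matches a motif and never forms a base pair. Soft-masking (lowercase) is
ignored.

## Motif enrichment

Occurrences are counted at **every** start position, so overlapping copies
(e.g. `TATAATATATAATATA` = two copies at offsets 1 and 8) both count;
`TATAATATA` is not its own reverse complement, so the default scan is
forward-strand only, with a `both` mode that also scans the motif's
reverse complement and deduplicates identical spans. A Hamming-distance-1
expansion flag covers near-variant motifs (e.g. `TATTATATA`); it changes no
default behaviour.

The null model is iid sequence with P(G)=P(C)=g/2, P(A)=P(T)=(1−g)/2,
regenerated from the **measured** length and G+C fraction of the region
under test (G+C rounded to 0.1%), so the test self-adapts rather than
assuming a fixed composition. The analytic expectation
E = (L − k + 1)·∏ᵢp(mᵢ) serves as an independent oracle for the
Monte-Carlo mean; for a 1692-nt region at 7% G+C it gives
1684 × 0.465⁹ ≈ 1.71 expected copies. Note that an observed-count mean of
~1.5–1.6 from any particular 25-sequence batch is within one Monte-Carlo
standard error of that expectation — small null panels are noisy, which is
why the default `n_samples=25` is kept for comparability but ≥1000 is
recommended for stable null means.

### Exact Wilcoxon signed-rank test

Paired differences (observed − nullᵢ) are formed, zeros dropped, absolute
values ranked with midranks for ties. For n ≤ 25 the p-value is exact: the
full distribution of W⁺ over all 2ⁿ sign assignments is built by dynamic
programming on a doubled-rank integer lattice (equivalent to explicit
enumeration, which the test suite performs independently for n ≤ 10).
Above n = 25 a normal approximation with continuity and tie corrections is
used. The test is two-sided by default — sidedness is a user decision, and
`greater`/`less` are available — so the smallest attainable p with 25
all-positive differences is 2/2²⁵ ≈ 5.96×10⁻⁸. When every difference is
zero the statistic is undefined and `None` is returned rather than a
value.

## Stem-loop detection (inverted-repeat model)

A hairpin is modelled as a local alignment between the sequence and its own
reverse complement: aligned complementary columns become base pairs
(strictly nested by construction; a validator enforces this on every
output), mismatch columns become 1×1 internal loops, gap columns become
bulges or asymmetric internal loops. This two-arm model captures the long
near-palindromic stems that matter for PATRR analysis; it is **not** a
minimum-free-energy folder — branched "mini stem loops" protruding from a
main stem are represented as internal loops, and their count is
approximate.

Scoring defaults are match +5, mismatch −6, gap open 15, gap extend 5.
These are deliberately stiffer than generic DNA-vs-DNA scoring (the
EMBOSS-like −4/10/0.5): an A+T-biased sequence is chance-complementary to
its own reverse complement at ~44% per position, and with cheap gap
extension the local alignment enters the linear (supercritical) regime and
percolates indefinitely through unrelated flanks — planted 294 bp
palindromes came back as ~570 bp "stems" under the permissive scoring.
After alignment, each pair chain is additionally trimmed outward from the
apex at its maximum cumulative score under the same scoring, which removes
residual chance extension. On a 50-case seeded grid (stems 50–300 bp,
loops 3–20 nt, up to three ≤5 nt internal loops) the detector recovers
stem size and apex length within ±3 in 48/50 cases.

Multiple stems are found greedily: best hit, mask its footprint, repeat
(up to `max_results`). Hits whose apex loop falls outside
[`min_loop`=3, `max_loop`=1000] or with fewer than `min_stem_bp` pairs are
discarded. Ties are broken leftmost-then-longest.

`gc_per_bp` is defined as n_GC_pairs / n_bp over the detected pair list —
stated explicitly because published per-structure values sometimes imply a
different denominator (a stem reported with 64 G:C bonds at 0.26/bp
implies ~246 bp, not the 294 bp quoted for the same structure; the
convention here is the literal pair count of our detected stem).

Strata are defined on the pair list ordered from the apex: upper third =
first ⌈n_bp/3⌉ pairs. The motif-near-apex flags test a 50-nt window
(`apex_window`) on each arm adjacent to the apex loop — "close to the
apex" has no standard quantification, so the window is a package default.

## Thermodynamics

Free energies are nearest-neighbor sums at 37 °C, 1 M NaCl: the ten unique
unified stack ΔG°₃₇ values, applied to consecutive pairs with no
intervening unpaired bases, plus a hairpin penalty for the apex loop and
internal-loop/bulge penalties per interruption. Loop penalties are linearly
interpolated within the published tables and log-extrapolated
(Jacobson–Stockmayer, 1.75·RT·ln(n/n_max)) beyond them. A symmetric 1×1
mismatch is charged 1.0 kcal/mol: loop initiation (~3.2) offset by the two
mismatch-stacking terms (~−1 each) that a full parameter set would apply;
without this offset, long marginally-paired A:T stems would be scored far
less stable than any folder predicts. The parameter-set name is recorded
in every feature row.

Two caveats. First, ΔG is computed for the detected inverted repeat, not
for an optimal fold, so values for weak chance stems can be positive
(honest: such structures would not fold). Second, published per-structure
ΔG values from MFE folders are reproducible only in rank order and rough
magnitude — e.g. a near-perfect 294 bp stem with moderate G:C content
scores ≈ −340 kcal/mol here against ≈ −320 reported by mfold for the
natural structure of that geometry. A toy note on tiny stems: a 2-bp stem
with an apex loop has ΔG > 0 because the loop penalty exceeds one stack;
`StemLoop.apex_loop` is optional so that bare stacked-pair constructions
(used in oracle tests) can be scored as pure stack sums.

## Translocation-propensity classifier

Five boolean criteria, all required for "high": stem ≥ 200 bp; apex loop
≤ 5 nt; ≥ 90% A:T pairs in the upper third; G:C fraction of the lower
two-thirds in [0.25, 0.55]; no internal loop > 10 nt per side. The
apex cutoff is **inclusive** ≤ 5 because the canonical high-frequency
exemplar itself has a 5-base apex loop while the qualitative criterion
says "small (<5 nt)" — inclusivity reconciles the two. The "moderate
~40%" G:C band is widened to [25%, 55%] so that a documented
high-frequency structure at 0.26 G:C/bp qualifies; the 10 nt interruption
cutoff sits above the tolerated 3 nt bulge of that exemplar. The
motif-near-apex flag is reported but never required — the motif is absent
from some translocating PATRRs. Under the two-arm model a "protruding stem
loop" is indistinguishable from a large internal loop and is treated as
one. The class is ternary (high/low/none) because the underlying evidence
ranks structures only qualitatively; `criteria_met` (0–5) is provided for
users wanting a graded value.

## Pairwise alignment and homology mapping

`global_align` is affine-gap Needleman–Wunsch (match +5, mismatch −4, gap
of length L costs 10 + 0.5L) with end gaps free by default, i.e.
EMBOSS-Needle-like. The engine is Biopython's `PairwiseAligner` (C
implementation); the test suite checks its scores against an exhaustive
alignment-path enumeration oracle for short strings. Tie-breaking among
co-optimal alignments follows the engine's deterministic internal order;
in A+T-rich low-complexity stretches co-optimal alignments are common, so
motif-fate categories in genuinely ambiguous columns are one valid choice
among several. Percent identity defaults to identical columns over all
columns excluding end gaps, to 1 decimal; an `all_columns` mode is
available since the denominator convention is never universal.

`local_map` is a BLAST-style mapper: exact k-mer seeds (k = 12), clustered
by diagonal (band 20, max along-query gap 400), each cluster extended by
aligning the query against a padded target window with free end gaps.
Hits below `min_identity_pct` (default 90) or shorter than `min_span`
(default 100 nt) on the target are dropped; overlapping target hits keep
the best score; minus-strand hits are reported in plus-strand target
coordinates with strand "−". No low-complexity masking is applied before
seeding (A+T-rich queries are the use case); defaults are strict enough
that shuffled targets produce no hits.

`classify_motif_fate` finds motif occurrences in both ungapped sequences,
projects them to alignment columns, and calls occurrences with identical
column spans conserved. For species-specific occurrences the cause is read
from the partner's aligned span: no gaps → substitution; extra partner
bases → insertion; missing partner bases → deletion; both → complex.
"Sequence addition" vs "oligo-insertion" distinctions collapse to
insertion. By construction, conserved + a_only equals the motif count of
sequence a (and likewise for b), which the pipeline cross-checks between
its enrichment and fate sections.

## A+T-rich segment detection

Sliding windows (default 100 nt) with A+T fraction ≥ 0.85 are merged when
overlapping or adjacent; merged spans < 300 nt are dropped. This automates
a delineation that is, in the motivating analyses, done manually from
cross-species alignment guideposts — the defaults are package choices, not
field constants, and user-supplied BED regions always take precedence in
the pipeline.

## Synthetic data

`make_variable_region` plants a requested number of motif copies at
uniform random non-overlapping positions (an overlap-allowed flag exists;
with it, later plants can clobber earlier ones, so the guaranteed-count
property holds only in the default mode) on an iid background; chance
background copies may raise the final count above the planted number, and
the truth records the planted subset.

`make_patrr` builds a stratified left arm (apex-proximal third at
`at_frac_upper` A+T, remainder at `gc_frac_lower` G:C), optionally writes
the motif and its reverse complement at the arm's apex end — which places
the motif in the linear 5'→3' reading adjacent to the apex on *both* arms,
as in natural PATRRs — then appends the apex loop and the arm's reverse
complement with any requested asymmetric unpaired insertions, inside iid
flanks. Loop and insertion bases are drawn from {A, C} so they cannot
pair with one another and blur the planted geometry.

`make_locus` assembles a 10,000 nt two-part locus: three 800-nt
breakpoint-flank-like inserts (one fixed random sequence per seed,
carrying 212-nt "exon" and 133-nt "intron" submotifs at fixed offsets)
alternating with three A+T-rich variable regions (1054/732/1100 nt at
~94% A+T with 38/20/26 planted motif copies — the copy-number scale of
the motivating locus), a 120 bp palindrome inside the third region, and a
conserved tail filling the remainder. The comparator is derived
per-region-class: conserved tail at 3% substitutions with no indels
(yielding ~97% alignment identity), variable regions at 15% substitutions
plus 2% indels (geometric lengths, mean 4 nt — the real indel process is
unquantified; "expanded greatly" is the only constraint), inserts either
lightly mutated (2%) or deleted outright (two of three, emulating
species-specific inserts). Substitutions always change the base. All
generators are deterministic per seed and emit JSON-serializable truth
with 1-based coordinates.

What the generator does **not** emulate: real low-copy-repeat context,
microsatellite slippage, segmental duplication history, alignment-breaking
tandem repeats, or selection. Passing tests on synthetic loci therefore
demonstrate that the machinery recovers known truth under the stated
mutation model — not that real loci are this clean; on real data the
A+T-rich regions are low-complexity enough that alignment non-uniqueness
("edge effects") makes per-motif fate calls convention-dependent.

## Pipeline and problem sizes

`run_all` executes: query mapping → region delineation → per-region
enrichment (plus comparator ratio and motif fate when a comparator is
given; the comparator homolog of each region is located by relaxed
`local_map`, min identity 50%) → stem detection/features/ΔG/classification
→ conserved-span identity. Reports are JSON plus TSV mirrors, carry a
provenance block (version, seeds, thresholds, thermodynamic parameter-set
name), contain no timestamps, and are byte-identical on rerun with the
same config. Any stage failure aborts with the stage name attached.

Default analysis sizes — a 10 kb locus, ~1 kb regions, 25-sequence null
panels, 10,000-sequence verification panels for the acceptance script — run
the full suite and pipeline in well under a minute each on a laptop-class
CPU; all simulations scale linearly if users raise them.

## Known limitations

* The inverted-repeat model cannot represent branched secondary structure;
  a genuine three-way junction appears as one stem with internal loops.
* ΔG values are comparable within this package, not with MFE folders.
* The exact signed-rank test assumes exchangeability of the null panel;
  with `n_samples` = 25 the p-value floor is 2/2²⁵.
* `local_map` with default thresholds is tuned for ≥90%-identity inserts;
  diverged homologs need relaxed settings (the pipeline does this for its
  comparator searches).
* The enrichment null is iid: it matches mononucleotide composition only.
  Dinucleotide-preserving (shuffle/Markov) nulls are out of scope.
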