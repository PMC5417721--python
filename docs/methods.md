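# Methods

## Model and scoring

`linmotif` treats motif discovery as an enrichment problem over a
three-way partition of a proteome. For a target protein or domain, the
*positives* are its *n* known binders, the *negatives* are the *p* proteins
that bind other members of the same family but not the target, and the
*background* holds the remaining *b* proteins. A protein that binds both
the target and another family member is a positive (positive status wins);
the three sets are disjoint by construction.

A motif is a fixed-length pattern of defined positions (one amino acid),
wildcards (`x`, any of the 20 canonical amino acids) and brackets (an
explicit 2–19 letter subset). Non-canonical letters (`B J O U X Z *`) are
retained in sequences but act as sentinels that match *no* motif position,
wildcards included, so ambiguity codes never inflate counts. Matching is
ungapped and exact; variable-length gaps are out of scope.

The "success" underlying all statistics is a *protein containing at least
one match* (presence, not occurrence count). With presence counts
k (positives), q (negatives) and m (background), the upper-tail cumulative
hypergeometric H(k | N, m, n) yields

* `p_NEG = H(k | n+p, k+q, n)` — enrichment over the negatives;
* `p_BAK = H(k | n+p+b, k+q+m, n)` — enrichment over the full proteome
  (default), or `H(k | n+b, k+m, n)` in `background_only` mode. Both modes
  are exposed because the two conventions give slightly different reference
  populations and users should state which they report.

When the negatives (or the background) set is empty only the other p-value
is produced and scoring proceeds on that axis alone.

All p-values are computed and stored in log10 space. The tail sum uses
log-gamma terms combined by log-sum-exp; when the tail carries most of the
probability mass the complement (lower tail) is summed instead and
converted through `log1p`, so `log10 p` keeps full relative precision both
for p near 1 and for p far below the double-precision minimum (~1e-308).
Degenerate cases are exact: k ≤ max(0, n+m−N) gives p = 1 and k > min(m, n)
gives p = 0.

Significance is relative: each axis's −log10 p is standardized (population
standard deviation) over *all* motifs surviving pruning in the run, pooled
across masks and lengths, and a motif's assigned score z is the *minimum*
of its two z-scores. A single-motif (zero-variance) population maps to
z = 0 rather than NaN. No multiple-testing correction is applied; the
population size is reported so users can adjust externally. Ranking is by
z descending, then stronger p_NEG, then motif text — deterministic for
identical inputs and configuration.

## Enumeration

Windows of length l are enumerated over the positives and passed through
wildcard masks. Two mask modes exist:

* `strict` — all 2^l boolean masks, the full combinatorial family;
* `canonical` (default) — the 2^(l−2) masks with defined first and last
  positions. A motif with a terminal wildcard is count-equivalent to its
  trimmed core (up to sequence-edge effects), so canonical mode avoids
  duplicated statistics and recovers full coverage by sweeping lengths.

Masks are processed strictly one at a time and each per-mask structure is
released before the next, which keeps peak memory linear in l rather than
exponential. Internally a mask's counting structure packs the residues at
the mask's defined columns into a base-21 integer key per window; distinct-
protein counts come from one vectorized sort over (key, protein) pairs, and
masks of one length are visited in Gray-code order so consecutive masks'
keys differ by a single vector add. The structure is behaviorally a
suffix-trie per mask; `node_count` reports the trie-equivalent size bound
(entries × (l+1) + 1) for memory diagnostics. Pruning at `min_occurrence`
(default 3: small enough for toy data, large enough to drop singletons)
happens before any negative/background scan.

## Degeneration search

Wildcards of promising motifs are grown into brackets: each wildcard is
substituted by each of the 20 amino acids, substitutions that improve the
motif's p-values are retained, and retained brackets are extended one amino
acid at a time while improvement continues; whenever a substitution at one
position improves, the other wildcard positions are explored from that
state, capturing correlated preferences. The search deduplicates states by
canonical motif text, never scores a motif twice, and terminates by strict
improvement over a finite lattice; a per-seed budget (default 50 000 scored
variants) guards pathological cases and reports truncation explicitly.

"Improvement" defaults to the composite rule: the worse (larger) of the two
log10 p-values must strictly decrease (ties broken by the other axis) —
consistent with the final min-z ranking. An `either` rule (any axis
improves) is available. z-scores are never recomputed inside the search;
improvement is judged on raw p-values and all returned variants are
re-standardized against the full population afterwards.

Variant counts are computed from the cached match windows of the seed —
a bracket variant can only match where its wildcard parent matched — which
is exactly equivalent to, and much cheaper than, a full rescan (the
equivalence is tested). A vectorized matcher over the concatenated
partition makes cache construction cheap when many seeds are processed.

Two knobs exist beyond the paper-style plain search, both off by default:

* **Selection margin** (`improve_margin`, log10 units). Greedy bracket
  growth picks the best of ~20 candidate letters at every step, so in a
  background-only setting each step can "absorb" a single chance-matching
  positive protein for a gain of about log10(N/n) while adding almost no
  background cost; left unchecked this manufactures wide brackets fit to
  sampling noise. Requiring each accepted step to gain more than a margin
  below that absorption quantum (the benchmark uses 0.7) suppresses
  one-protein absorption while keeping letters that carry two or more
  planted/biological proteins.
* **Seed screening and extension** (`degenerate_screen`,
  `extension_rounds`). Degenerating every enumerated motif is exhaustive
  but intractable at desk scale. The screen ranks candidate seeds
  population-wide using already-computed child counts (a motif extended by
  one defined letter is itself an enumerated motif one length up): summing
  the best letters' positive counts against their reference counts bounds
  the enrichment a bracket could reach at that position. The strongest
  candidates are padded with terminal wildcards so flanking positions are
  degenerable, searched, and the best improved variants are re-padded and
  re-searched for a few rounds — letting bracket chains grow outward to
  motifs much longer than their defined skeleton.

## Selection and evaluation

Ranked motifs are selected greedily under a global coverage budget: a motif
is selected iff it contributes at least one newly covered residue, and
selection stops at the first motif whose addition would push the total
covered length past `budget_fraction` × total positive length (default 3%,
comparable to the footprint of annotated binding sites). For evaluation
against annotated sites, every covered residue's distance to the nearest
site interval is computed (0 inside a site; residues on proteins without
sites go to a separate infinity bin), histogrammed in 10-residue bins, and
summarized as the fraction within sites and within 10 residues.

The planted-motif benchmark uses capped precision instead: per-motif match
position sets are accumulated in rank order until coverage reaches the
number of planted positions (the crossing motif is included in full; a
truncate-at-cap variant exists), then precision = TP/(TP+FP) over planted
positions, with success at precision ≥ 0.7. Because canonical-mode cores
strip terminal wildcards, each ranked motif's terminal-wildcard padded
variants (count-equivalent, hence equal-scored adjacent ranks in a strict
2^l enumeration) are interleaved after it during accumulation.

## Synthetic benchmark

Eight curated ELM-database consensus motifs (4–11 residues, 1–6 ambiguous
positions) are packaged. For each benchmark cell a motif's ambiguous
positions are expanded into all concrete combinations; combinations are
sampled without replacement while any remain (maximizing planted
diversity), then with replacement; each is written at a uniform offset into
a distinct sequence — at most one insertion per sequence — overwriting only
defined and ambiguous columns, wildcard columns keep the underlying
residues. The full design is 8 motifs × 4 occurrence levels (5, 10, 15,
20) × 20 replicate sets of 50 sequences = 640 sets.

The generator emulates sampling a homology-reduced proteome: i.i.d.
residues with lengths uniform in 100–500. The benchmark draws residues at
S. cerevisiae proteome frequencies because composition matters — rare
residues (C 1.3%, W 1.0%, M 2.1%) anchor several packaged motifs and a
uniform alphabet would erase precisely that signal; the generator's own
default stays uniform for neutral use. Real sequences can be supplied
instead through a FASTA mode with a greedy shared-k-mer diagonal screen
rejecting ≥50% identity over ≥50 aligned residues (a documented
approximation of an alignment-based homology filter). What i.i.d. draws do
*not* emulate: tandem repeats, low-complexity regions, residual homology
and naturally occurring motif instances — all of which inflate background
counts for recurrent patterns in real proteomes. Passing benchmark results
therefore demonstrate the pipeline's statistical machinery under clean
conditions, not performance on biological sequence.

Benchmark discovery runs blind per set: positives = the 50 planted
sequences, negatives empty, background = 950 disjoint generated sequences
(mirroring the 1000-sequence pool the design samples from). Core
enumeration uses canonical masks for l = 2–8 — the longest defined skeleton
among the packaged motifs spans 7 residues — with degeneration, screening
(48 seeds), four extension rounds and padding growing variants up to
length 11, bracket width capped at 8 (the widest packaged ambiguity set has
7 letters), and the 0.7 selection margin. A cell succeeds at capped
precision ≥ 0.7; discovery accuracy per (motif, occurrences) is the
fraction of successful replicates, and a motif counts as "identified" at an
occurrence level when accuracy exceeds 0.5 (the cutoff is configurable; the
threshold behind published bar charts is not stated anywhere recoverable).

Known limitation: at 10 occurrences, motifs whose defined skeletons are
common two-letter anchors with wide ambiguity sets (`P[MVLIRWY]V[MVLIAS][LM]`,
`xRxx[PGAV][DEIP]Gx`, `[FHYM]xA[AV]x[VAC]L[MV]x[MI]`) have full-pattern
p-value ceilings around 1e-8 under this generator, while the enumeration's
own chance-motif order statistic across ~14 500 windows × 127 masks reaches
1e-10–1e-12 (patterns hitting ~9 of 50 positives and none of 950
background). Enrichment ranking therefore cannot place them on top at that
occupancy regardless of search quality, and three further motifs
(`[FY][DEP]WM`, the Csk-site pattern, the length-11 Sin3 pattern) sit with
ceilings *at* the chance floor, succeeding only in favorable realizations
(accuracy 0.1–0.25 over 20 replicates). At 10 occurrences the benchmark
reliably identifies the motifs with rare-residue or dense defined anchors
(`xP[TS]APx`, `GCM[GS][CL][KP]C`); at 15–20 occurrences planted ceilings
(1e-13 and beyond) clear the chance floor and recovery broadens, giving
the characteristic accuracy-vs-occupancy growth the sweep verifies.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; site tables must declare
  their convention in the header (`start`/`end` = 0-based half-open,
  `start_1based`/`end_1based` = 1-based inclusive, converted on input).
* Log10 p-values are clipped at −320 only for z standardization (keeping z
  finite when p underflows even in log space); ranking tie-breaks use the
  unclipped values, so arbitrarily small p-values still order correctly.
* Candidate letters are tried in alphabetical order; equal-objective
  candidates are not retained (strict improvement); bracket text renders
  alphabetically, so equal motifs always render identically.
* All randomness flows from explicit seeds; per-cell seeds fan out from the
  master seed by stable hashing, so any benchmark cell can be regenerated
  in isolation and identical configuration reproduces byte-identical
  outputs.
* Integer window keys support up to 13 defined columns per mask; the rare
  denser masks (near-fully-defined motifs of length 14–15) use an
  equivalent dictionary-based fallback.
* Problem sizes in the shipped acceptance run — 8 × 20 benchmark cells at
  10 occurrences, a 2-motif × 4-level × 4-replicate sweep, exhaustive
  hypergeometric verification to N = 60 plus 1000 random cases to
  N = 10 000 — are the package's chosen desk-scale defaults; every piece
  scales up by configuration only.
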