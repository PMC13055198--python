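# Methods

## Model and score

`compmatch` treats a protein region as a point in the 20-dimensional
simplex of percent amino-acid composition and measures similarity to a
query as compositional identity,

    CI = 100 - D1(q, s) / 2,

where `D1` is the Manhattan (L1) distance between the query's and the
subject window's percent-composition vectors over the canonical amino
acids. Because each vector's entries sum to at most 100, `D1` lies in
[0, 200] and CI in [0, 100]; CI is symmetric, equals 100 exactly iff the
compositions coincide, and is invariant under any permutation of either
sequence. That permutation invariance is the operating assumption of the
tool: for composition-driven activities, residue order is treated as
irrelevant and similarity is scored purely on composition. CI says
nothing about activities that depend on sequence patterning; it is a
search score, not an activity predictor.

The proteome search slides every window size `w` in
`[min_window, max_window]` over every protein, computes each window's
composition, and keeps the single best window per protein — one region
per protein, never multiple non-overlapping hits. The query composition
is computed once over the full query sequence as given, even when the
query's length falls outside the window range.

## Parameters

- `min_window`, `max_window` (residues; default 90–120 inclusive). The
  default range brackets functional disordered domains: short enough to
  sit inside a single IDR, long enough that percent composition is a
  stable summary. Windows are inclusive at both ends; a protein shorter
  than `min_window` is skipped and logged.
- `metric` (`manhattan`, default, or `euclidean`). Ranking uses the
  selected metric; the reported `ci` column is always the Manhattan-based
  quantity, because CI is defined only in Manhattan terms. Under the
  Euclidean metric the raw distance column disambiguates the ranking
  key. The two rank-comparison operations (`rank_percentile`,
  `rank_difference`) quantify how much a ranking moves across window
  ranges or metrics.
- `strict_noncanonical` (default off). Non-canonical residues (X, B, Z,
  U, O, J) contribute to window length but to no canonical percent, so
  by default they dilute a window's composition and degrade CI
  gracefully without fabricating canonical content. Strict mode instead
  discards any window containing one; a protein with no clean window is
  then skipped. Dilution is the default because it never invents
  composition and keeps every protein searchable.
- Alignment scoring (pairwise module): BLOSUM62, gap open 10, gap extend
  0.5, end gaps free — the standard global-alignment defaults for
  percent identity. Identity uses the full alignment length, gap columns
  included, in the denominator. All four knobs are configurable through
  `AlignmentScoring`.
- Prominence threshold (default 10%): an amino acid is a prominent
  feature of a match when its percent strictly exceeds the threshold in
  the query or the matched window. The boundary is exclusive: exactly
  10.0% does not qualify.

## Algorithm and numerics

Per protein the scan one-hot encodes the sequence into 21 integer
columns (20 canonical + 1 non-canonical) and takes a prefix sum, so the
residue counts of every window of size `w` are two-row differences and
each window size costs O(L) rather than O(L·w). An equivalent
incremental single-window update (`slide_counts`) is exposed and tested
against from-scratch recounts. The number of windows evaluated for a
protein of length L is `sum_w max(0, L - w + 1)` — linear in proteome
size for a fixed window range, and quadratic-ish in window count as the
range widens (`n_windows` computes it exactly).

Window percents are computed as `counts * 100.0 / w` and distances as
numpy reductions over the 20 canonical entries; the test suite holds the
scan to *exact* float equality with an independent exhaustive search
that recounts every window, which both paths satisfy because they
perform the same arithmetic on the same integer counts. Internal
arithmetic is full double precision; only rendered output is rounded
(4 decimals), since CI gaps between neighboring ranks can be small.

Tie-breaking is deterministic and documented rather than inherited:
within a protein, smallest distance first, then leftmost start, then
largest window size (the larger window carries more flanking context for
downstream cloning-style use). Across proteins, ties break by protein id
ascending lexicographically, making rankings reproducible across runs,
platforms, and input orderings. Reported coordinates are 1-based
inclusive, matching wet-lab convention; internal arithmetic is 0-based
half-open.

Degenerate inputs are errors, not warnings: empty proteomes, queries
with no canonical residue, duplicate FASTA ids, empty sequences, and
internal stop symbols all raise. Terminal stop symbols are stripped;
lowercase (soft-masked) sequence is uppercased.

## Synthetic data

The generator emulates the one property the search needs from a
proteome: many unrelated background proteins plus, optionally, a single
region of exactly known composition. Background proteins draw residues
i.i.d. from a background composition; the shipped
`CHARGED_BACKGROUND` (20% D, 20% E, 18% K, 17% R, 10% A, 8% L, 7% V) is
deliberately depleted of uncharged polar residues — a worst-case,
compositionally remote backdrop for a polar-IDR query. `plant_region`
overwrites a random slice of one protein with a random permutation of an
exact residue multiset realizing the target composition
(`QN_RICH_TARGET`: 40% Q, 30% N, 10% S, 10% G, 5% Y, 5% P at window
100, a prion-like-domain-style profile). Compositions that imply
non-integer counts at the chosen window are rejected rather than
rounded, so the CI-100 optimum of a matching query is exact ground
truth. All generators are pure functions of spec plus seed. Replicate
counts and sizes used by the tests and the acceptance script (50
replicate proteomes of 1,000 proteins, lengths 200–600; 100
oracle-comparison proteins of length ≤ 300) are desk-scale choices that
keep a full run in minutes on one CPU while leaving the recovery and
equivalence checks statistically meaningless to pass by luck.

What the synthetic data does *not* emulate: real proteomes have
length-dependent composition, repeats, domain structure, and regions
intermediate between query and background, so real searches produce
graded CI spectra rather than the 100-versus-0 separation seen in the
fixtures. Passing the planted-recovery tests shows the scan finds an
exact-composition optimum under adversarially remote background; it does
not validate biological ranking quality on real proteomes, which depends
on how strongly the activity of interest is composition-driven.

## Design choices where the design was open

- FASTA ids are the first whitespace-delimited header token kept intact
  (no UniProt pipe-splitting): lossless and collision-free. Duplicate
  ids are rejected rather than silently suffixed.
- The rank-percentile convention is `100 * (N - rank + 1) / N`, chosen
  so a search's own top hit scores exactly 100 and percentile decreases
  strictly with rank.
- A planted region is a *permutation* of the target multiset, not a
  resampling, so planted-versus-query comparisons have CI exactly 100
  while global-alignment identity stays low (empirically ~30–50% for the
  shipped 6-letter Q/N-rich target at window 100) — the dissociation the
  pairwise module is designed to expose.
- The CLI is a thin layer over the library; all computation is
  importable, and the `#`-comment header in results files records the
  tool version and full parameter set so any output is reproducible from
  its own provenance block.

## Limitations

- CI compares whole-window composition only; it cannot distinguish
  sequences that differ in patterning, charge blockiness, or motif
  content at equal composition.
- No statistical significance is attached to CI values: there is no
  null model, so ranks are relative within one search, not calibrated
  across proteomes or queries.
- The scan reports exactly one region per protein; proteins with two
  strong, distinct composition-matched regions surface only the better
  one.
- Global-alignment identity among co-optimal alignments is taken from
  the aligner's first reported alignment; co-optimal alignments can
  realize different identities (the tests assert membership in the
  enumerated optimal set, not uniqueness).
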