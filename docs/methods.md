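# Methods

`playnet` quantifies the *coherence statistics* of dyadic toy-selection
time series: whether the stream of referential acts a toddler and parent
produce during free play is temporally and relationally structured
beyond what the skewed popularity of individual toys would produce on
its own.

## Data model

A session is coded on a fixed grid of `n_segments` 5-second bins
(default 121, i.e. a ten-minute session).  A *selection event* is a
4-tuple `(toy, agent, act, segment)`; the three coded behaviours are
toddler handling, parent handling and parent talk about a toy (toddler
talk is not coded).  Events are unique within a dyad — the same act in
the same segment is one event, and an act spanning two bins is coded
upstream as two events.  The toy universe defaults to the observed toys
padded with placeholders to 32, so that whole-universe rank statistics
(Spearman over 32 toys, df = 31) are well defined.

## Frequency statistics and the Topic/Comment partition

Per behaviour stream we build rank-frequency tables (proportions of the
stream total).  Two within-dyad comparisons are computed for each pair
of streams:

* a Wilcoxon signed-rank test on the *rank-aligned* frequency vectors
  (frequency at rank i in one stream paired with frequency at rank i in
  the other, zero-padded to the universe size).  This pairing ignores
  toy identity and compares only distribution shape; the reported `V`
  follows the R convention (rank sum of positive differences, zeros
  dropped).  The zero-difference and tie policies are a package choice;
  other conventions shift `V` slightly.
* Spearman's rank correlation on per-toy counts over the full universe,
  zeros included, average ranks for ties.

The *Topic* set is the dyad's five most frequently selected toys by the
aggregate count over all behaviours; everything else selected is a
*Comment* toy.  Ties at the boundary are broken by earlier first
selection, then lexicographically, so the partition is invariant to
input row order.

## Clusters and the permutation null

For each toy we collapse events to a boolean per-segment occupancy
vector; a *cluster* is a maximal run of at least two consecutive
occupied segments and its *run length* is the run's segment count
(multiply by 5 for seconds).  Per category we report the mean number of
clusters per toy and the mean run length over clusters; per-dyad totals
are also available.  An alternative reading that averages per toy with
zero-padding, or counts singleton runs, can be obtained through
`min_run` and the returned run-length lists.

The null model permutes toy labels across all of a dyad's events while
holding the (agent, act, segment) scaffold fixed.  Each permutation
conserves exactly: the total event count, the per-segment event counts,
and the per-toy aggregate frequencies — the null that the temporal
statistics are a consequence of frequencies alone.  A label shuffle can
collide (two events sharing a segment-behaviour slot drawing the same
toy, which would merge them); plain rejection sampling is exact and is
tried first, but under realistic skew collision-free shuffles are
vanishingly rare, so remaining collisions are resolved by uniformly
proposed label swaps accepted only when they remove a collision without
creating one.  The repaired draw conserves the label multiset exactly
and is validated empirically: on memoryless (i.i.d.) series the observed
cluster count falls inside the central 99% of its own 10,000-permutation
distribution in ≥95% of replicates, and on tiny series the sampled
distribution matches exhaustive enumeration over all valid label
assignments (χ² goodness of fit).  The baseline default is 10,000
permutations per dyad; ensembles are reproducible given a seed.

## Quartile profiles and cross-recurrence

The session is split into quartiles of 30/30/30/31 segments (2.5 min
each, remainder to the last).  Within each quartile the dyad's score per
category is the proportion of that quartile's selections going to the
category, divided by 5 for Topics and by the number of referenced
Comment toys for Comments.  Per-rank Topic profiles (share of the
quartile's Topic selections per rank) accompany the category scores.

Cross-recurrence lags are computed over *all* pairs of a toddler
handling event and a parent handling-or-talk event on the same toy:
`lag = (parent segment − toddler segment) × 5 s`, positive when the
toddler selected the toy first.  The lag multiset, its positive-lag
proportion, and per-category mean lags are reported.

## Transition networks

Every unordered pair of distinct events in the same segment, plus the
full cross product of events in adjacent segments, is a transition pair:
S (same toy, a self-loop) or D (different toys, an edge).  Orientation
is never distinguished.  Accumulated pair counts give a weighted
undirected toy graph per dyad; the *Random* network takes as weights the
mean S/D pair counts over the permutation ensemble (fractional, total
conserved).  Node measures:

* `s_strength` / `d_strength` — self-loop weight and summed incident D
  edge weight;
* `degree` — distinct neighbours with weight above the presence
  threshold (default 0; self-loops never count);
* `betweenness` — raw shortest-path counts on the binarized graph,
  endpoints excluded, fractional over multiple shortest paths,
  unnormalized (the hop-count reading of shortest paths);
* `clustering` — local clustering coefficient.  The default is the
  weighted (Onnela geometric-mean) coefficient on the weighted D graph
  rather than the binarized one: a permutation-mean network carries many
  vanishing fractional edges, and binarizing at threshold 0 would make
  it near-complete with clustering pinned at 1, an artefact of the
  averaging rather than a property of the null.  Binary clustering and
  the binarized graph transitivity are also emitted.

## Group-level contrasts

Every Observed×Random, Topic×Comment contrast is a fully within-subject
two-way ANOVA on per-dyad cell means (df2 = n_dyads − 1 for 2×2
designs); the quartile analysis is the 2×4 analogue.  The decomposition
tests each effect against its own subject-by-effect interaction; no
sphericity correction is applied (trivially satisfied for two-level
factors; reported uncorrected for the quartile factor).  p-values are
reported at full precision — the α = 0.01 convention of the study design
is an annotation, not a filter.  Dyads with incomplete cells (e.g. no
Comment clusters anywhere) are dropped from that contrast with a logged
warning.

## The synthetic dyad generator

The generator is a minimal mechanism reproducing the four signatures the
analysis assumes — skewed frequencies, bursty runs, long-lag returns,
and close-in-time partner coupling — not a cognitive model, and none of
its parameters are fitted to data.  Per segment the event count is
Poisson(`events_per_segment_rate`, default 2.4) split among the three
behaviours in proportions 0.40/0.33/0.37 (normalized).  A focal toy
persists across segments with probability `persistence_rho` (0.65) and
is otherwise redrawn from a reinforced urn: never-selected toys with
probability `novelty_alpha` (0.2) scaled by the unplayed fraction,
otherwise existing toys with weight `count^reinforcement_gamma` (0.25).
Individual events land on the focal toy with probability `focus_prob`
(0.5) or draw from the urn; parent acts copy the toddler's current or
previous focus with probability `coupling_kappa` (0.5) and their
non-coupled focal references trail the focus by one segment, so toy
introductions are toddler-led.

Defaults were calibrated once against the study-scale descriptives
(~90% occupied segments, 15–18 unique toys per stream, top-five share
around 60% against a reported mean of 57%, range 43–82%) and then
frozen.  Known gaps between generator and real data, and hence what
passing tests do *not* show about real sessions:

* the real sessions' per-toy selection counts are considerably higher
  than Poisson(2.4) produces; observed-vs-random margins (especially
  cluster counts and weighted clustering) are therefore much smaller
  here than the study-scale effects, and at this event density Comment
  toys are sparse enough that their observed cluster count sits *above*
  its random baseline rather than below;
* the toddler-leads asymmetry is reproduced in mean lag (Topic mean
  around +3–4 s) but only weakly in the all-pairs positive proportion
  (~50–51% rather than ~55%);
* parents in the generator handle slightly *fewer* unique toys than
  toddlers, the reverse of the real asymmetry.

`simulate_null` draws selections i.i.d. across segments from a given
toy distribution at the same Poisson rate; it is the calibration target
for the permutation engine.

## Numerical and design choices

* All randomness flows through seeded NumPy generators; cohort runs
  spawn per-dyad seeds from one `SeedSequence`, and every ensemble is
  replayable from its seed.
* Degenerate inputs: empty behaviour streams yield flagged empty
  rank tables rather than errors; a lag profile with no shared toys is
  flagged empty; zero-variance ANOVA cells give F = 0 (not NaN), and a
  positive effect over a zero error term gives F = ∞.
* Problem sizes in the shipped tests and the acceptance script (cohorts
  of 32 dyads, 150–10,000 permutations per dyad, 40–100 replicate
  seeds) are chosen so the full suite runs in minutes on one core while
  keeping Monte-Carlo error well below the asserted margins.
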