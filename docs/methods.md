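# Methods

## Model

A query compound q is related to a candidate target gene g through a
reference drug space of D drugs with known targets.  Two profile
vectors, both indexed by the drug space's fixed order, are correlated:

* **Structure profile** `s_q`: Tanimoto coefficient |A∩B|/|A∪B| between
  q's fingerprint and each reference drug's.  Fingerprints are plain
  feature sets — circular atom environments of radius 0–2 (atoms typed
  by element and heavy-atom degree) when parsed from SMILES with RDKit,
  or arbitrary precomputed tokens.  Binary set semantics are used
  throughout (no counts, no folding to fixed bit widths); downstream
  code consumes only set overlap, so any set-valued descriptor family
  is compatible.  Two empty fingerprints score 0, not 1: an empty set
  carries no evidence of similarity.

* **Functional profile** `f_g`: for each drug i with target set `T_i`,
  `f_g[i] = Σ_{t ∈ T_i ∩ V} K(L(g, t))` with L the unweighted
  shortest-path length in the protein-interaction network (node set V)
  and K a decaying kernel.  The default is Gaussian, `K(L) = exp(−L²)`:
  a gene that is itself a target contributes 1, a direct neighbor
  exp(−1) ≈ 0.37, a distance-2 gene exp(−4) ≈ 0.018, and unreachable or
  out-of-network targets 0.  `exp(−L)` and `1/(1+L)` are selectable in
  config; the Gaussian is the default because its sharp decay keeps
  functional similarity a local, neighborhood-scale notion, which is
  what "functionally related proteins interact" justifies.  Summation
  (not max) over a drug's targets lets multi-target drugs spread their
  evidence.

The concordance score is the Pearson correlation of `s_q` and `f_g`
(Spearman selectable).  Per compound, every network gene is scored and
ranked by decreasing score.  Profiles of length < 3 are rejected; a
profile with zero variance (e.g. a query sharing no feature with any
reference drug) yields a *degenerate flag* (NaN) rather than a score of
0 — a constant profile carries no concordance evidence and must not
outrank genuinely anti-correlated genes.  Degenerate entries sort after
all real scores; ties break by ascending gene identifier, so rankings
are bit-reproducible.

Functional profiles are query-independent, so the (|V| × D) profile
matrix is computed once per drug space + network (one BFS per distinct
target gene) and reused across all compounds; ranking a compound is then
a single vectorized correlation.

## Selection, pooling, characterization

Top-k% selection takes the first `max(1, ⌊fraction·N⌋)` ranked genes
(N = network size), excluding degenerate entries.  The floor-with-
minimum rule is deterministic and monotone in the fraction.  Pooling
across compounds takes the union of per-compound selections and records,
per gene, how many compounds selected it; the mean of these counts is
the "compounds per target" summary.

The pooled set is characterized with exact hypergeometric tails,
`P(X ≥ k)` (enrichment) or `P(X ≤ k)` (depletion) for
X ~ Hypergeometric(N, K, n), evaluated through scipy's log-space
survival/cumulative functions.  Conventions:

* **Universe.**  For gene-set collections: network nodes ∩ union of the
  collection's members, restricting the test to annotatable genes.  For
  known-target and hub analyses: all network nodes.  Both are
  overridable.
* **Significance** is the raw p < 0.05 rule; a Benjamini–Hochberg
  column is emitted alongside for reference but does not drive the
  reports.  Gene sets are ranked by increasing p.
* **Coverage** is k/K, the fraction of a set's (universe-restricted)
  members present among the candidates, printed to 4 decimals.
* **Known drug-target sets** are built by ATC prefix: the union of
  target sets of drugs with any code matching the prefix,
  case-insensitively ("C" = cardiovascular first level).
* **Hub depletion** is lower-tailed against the top-5% nodes by degree
  or normalized betweenness, ties broken by metric then identifier.
* A lower-tail p of an impossible event (k below the hypergeometric
  support) is reported as the smallest positive float rather than 0.

Betweenness uses the unordered-pair normalization
`B(n) = [Σ_{s≠n≠t} σ_st(n)/σ_st] / [(N−1)(N−2)/2]` — the middle node of
a 3-path and the center of a star are exactly 1.  Pairs with no
connecting path contribute 0 while N stays the full node count; graphs
with fewer than 3 nodes are rejected.  Networks load from two-column
edge lists as undirected simple graphs: self-loops are dropped (they
carry no distance information; nodes appearing only in self-loops vanish
with them), duplicate and reversed edges collapse, and the load report
records counts and connected-component sizes.  All components are kept;
distances are unweighted hop counts since interaction data carry no
usable edge lengths here.

The echocardiographic utility `fs_percent` computes left-ventricular
fractional shortening, `FS% = 100·(LVEDd − LVEDs)/LVEDd`, and rejects
LVEDs > LVEDd (negative shortening) instead of returning it silently.

## Synthetic worlds

The generator builds worlds in which the method's premise holds by
construction, with planted truth at every stage:

* **Network**: Barabási–Albert preferential attachment — connected,
  scale-free, heavy-tailed degrees like real interactomes.  Default
  1000 nodes, attachment 3 (mean degree ≈ 6, the right order for
  curated human interactomes at desk scale).
* **Drug space**: 200 drugs in 20 structural families.  Each family has
  a core feature set; a drug keeps a sampled fraction 1 − noise of it
  (noise default 0.3) and fills up with private random features to 30
  features per drug, from a universe of 2000 tokens — tens of atom
  environments per drug-like molecule, sparse overlap between unrelated
  ones.  Each family also has an anchor node; every family drug samples
  4 targets from the anchor's closed radius-1 neighborhood (expanded
  with a warning if too small).  Four targets per drug matches the
  ~3.9 interactions-per-drug density of curated drug-target spaces.
  Thus chemical similarity and target proximity co-vary — the planted
  assumption.  30% of drugs are tagged with an ATC "C" code so the
  known-target analysis has a non-trivial reference set.
* **Queries**: each copies a random drug's fingerprint, resampling a
  `perturbation` fraction of features (default 0 — the leave-one-out
  design); planted truth is the source drug's target set.
* **Gene sets**: 50 random 40-gene sets plus one planted set (the
  pooled planted targets) that enrichment must rank first.

Every generator is a pure function of (parameters, seed); a world's
component seeds are `seed … seed+3`, and evaluation utilities that need
extra randomness (null fingerprints) continue the sequence at `seed+4`.

What the worlds do **not** emulate: realistic chemical-space statistics
(feature tokens are exchangeable, real substructures are not), database
scale (10⁵ interactions), annotation hierarchies (gene sets are flat,
as in GMT; no ontology propagation), identifier namespace mapping, or
dose/ADME effects.  Passing tests therefore demonstrate that the
machinery is correct and that the method recovers its own planted
assumption — not that the assumption holds for any particular real
compound collection.

Two empirically observed subtleties of this design, documented because
they will surprise users who treat the dials as one-way:

* **Feature noise is not a clean degradation dial.**  Raising noise
  weakens family-level similarity but *adds* within-family
  discrimination (drugs stop being exact copies), which helps recover a
  specific drug's own targets in leave-one-out evaluation.  Only the
  query-perturbation axis degrades recovery monotonically; the property
  test sweeps that axis at fixed noise.
* **Null queries are only approximately uniform.**  For fingerprints
  drawn independently of the space, a single chance overlap with a
  family's core features correlates the query with the whole family
  block, so null hits cluster by family and the gene-level hit rate
  runs slightly above the uniform baseline.  This is a genuine property
  of correlation scoring on block-structured drug spaces, not a bug;
  the calibration check uses binomial bounds wide enough to be a fair
  test of gross miscalibration.

## Problem sizes and tolerances in the test bench

The test suite exercises the default 1000-node / 200-drug / 50-query
world (a scale at which the full suite runs in about a minute), plus a
200-node world for pipeline-level tests and 6–12-node graphs for the
exhaustive betweenness oracle.  Exactness checks: betweenness vs
explicit shortest-path enumeration within 1e−12; hypergeometric tails vs
integer binomial-coefficient sums within 1e−10 relative, including the
complementarity identity `P(X≥k) + P(X≤k−1) = 1`.  Calibration checks
use two-sided 99% binomial bounds.  Depletion calibration draws
200-gene candidate sets: with the 50-hub top-5% set of a 1000-node
world, smaller samples make the discrete lower tail degenerate (even
k = 0 has p > 0.05), which would leave nothing to calibrate — a power
consideration settled analytically at design time.

## Known limitations

* The concordance score has no per-gene significance; ranks are the
  output, and nearby non-targets of a true target's neighborhood rank
  high by construction.  This is inherent to the functional-profile
  locality, not an implementation artifact.
* Drugs whose targets all fall outside the network contribute a zero
  profile column; queries resembling only such drugs degrade toward the
  degenerate flag.
* Betweenness is exact Brandes, O(N·E) — fine to ~10⁴ nodes, not tuned
  beyond that; no approximation is provided.
* ATC matching is string-prefix only; no code-hierarchy validation.
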