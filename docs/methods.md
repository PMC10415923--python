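# Methods

## Profile model

A case profile is a set of alterations, each a
(gene, alteration class, protein change) triple tagged with an origin
(`key` = clinically curated finding, `vus` = variant of unknown
significance). Gene symbols are uppercased on ingest; no alias resolution
is attempted, so inputs must use consistent symbols. Protein changes are
compared as strings (no HGVS normalization) and only exist for the
`mutation` class. Triples are unique within a profile; when the same
triple is reported under both origins the key origin wins, on the grounds
that the key set is the curated one. The *total profile* — the matching
query — is simply the stored set; key/VUS views are derived.

Consensus profiles over a case series use a majority rule: a triple
enters the consensus when it appears in ≥ `min_fraction` of cases
(default 0.5, ≥ comparison). `min_fraction = 1` gives the intersection,
`min_fraction ≤ 1/n` the union. Consensus is taken per triple, not per
gene, so two different mutations of one gene are counted separately.

Timelines accept ISO-8601 dates only; one dialect avoids locale
ambiguity. Sorting is stable, so same-day events keep input order.

## Connecting score and communities

The connecting score of sample $S$ against profile $P$ is
$|\{a \in P : \exists b \in S, a \sim b\}| / |P|$: each case alteration
counts at most once no matter how many sample alterations satisfy it, and
the denominator is the (optionally gene-subset-restricted) case
alteration count. The match relation has three resolutions — gene,
gene + class, gene + class + protein change — with the last degrading to
the second for non-mutation classes, since protein changes are undefined
there. Score 1 therefore means the sample carries the whole (restricted)
profile; 0 means gene-disjointness. The complementary quantity
1 − score is exposed as `distance` for display only.

The DT+ community is `score ≥ cutoff` (a sample exactly at the cutoff is
a twin); ties in the score ordering are broken by sample id so output is
deterministic. Pre-match filters are a conjunction of per-feature
criteria; samples missing a filtered feature fail the criterion
(conservative exclusion, logged). Hybrid tumor + cell-line pools are
plain concatenations with a `source` tag — no special path. Extended
profile matching blends the genomic score with the fraction of agreeing
biomarkers among those present on both sides
(`w · genomic + (1 − w) · agreement`, default `w = 0.5`; numeric
biomarkers agree within a factor of two, MS status on equality). The
blend weight is a package choice; there is no field convention for it.

## Propensity balancing

"Match the un-matched" estimates P(DT+ | features) by maximum-likelihood
logistic regression (Newton iterations, ≤ 100, log-likelihood tolerance
1e-8; categorical features one-hot encoded, constant columns dropped with
a warning, rows with missing features dropped with a warning). Under
perfect separation the MLE diverges, so the fit falls back to an
L2-penalized logistic regression (penalty 1e-4, intercept unpenalized)
and is flagged `converged = False`. The intercept-only model reproduces
the treated fraction exactly (MLE score equation), which the tests use as
a closed-form anchor.

Matching is greedy 1:1 nearest-neighbor without replacement on the raw
propensity scale: treated units in descending propensity order, distance
ties broken by control id, optional caliper (a pair exceeding it is not
formed and the treated unit is recorded unmatched). Greedy matching is
the common default in applied propensity workflows and is deterministic
given inputs; optimal matching and weighting are out of scope. Balance is
diagnosed by the standardized mean difference
SMD = (mean₁ − mean₂) / √((var₁ + var₂)/2) with sample variances and
0/0 ≡ 0.

Mutant-vs-wildtype grouping for gain/loss analyses defines mutant as "any
mutation-class alteration in the gene" and wildtype as "no alteration in
the gene at all"; samples carrying only copy-number/fusion events of the
gene are excluded from both groups, since such events do not establish
the mutant genotype being tested. Fewer than `min_group = 3` mutants
yields a refusal marker rather than a fit — small mutant groups simply
cannot support the comparison, and the refusal is data, not an error.

## Enrichment and proximity

Signature enrichment is one-sided hypergeometric over-representation
against a user-selected background panel of size N: with K signature
genes and n query genes in the background and k in the overlap, p =
P(X ≥ k), X ~ Hypergeometric(N, K, n), computed through the log-gamma
survival function (exact to ≥ 10 significant digits for N ≤ 1e5, checked
against subset enumeration for small N). Each of the key/VUS/total views
is tested against every signature; Benjamini–Hochberg adjustment is
applied within each view across signatures, and both raw and adjusted p
are reported so either significance convention is readable. Query genes
outside the background are dropped (standard over-representation
convention, logged); signatures disjoint from the background are skipped
with a warning rather than tested vacuously.

Spatial grouping bins profile genes by (chromosome, arm) from a
gene → cytoband annotation and reports member genes, origin composition
and counts; genes without annotation are listed as unplaced. This
surfaces proximity clusters (e.g. several VUS genes on one arm) without
claiming any statistical model for co-location.

## Comparative statistics

* **Wilcoxon rank-sum** (scipy): exact enumeration permitted for
  nx + ny ≤ 20 without ties, otherwise the tie- and continuity-corrected
  normal approximation. Exact p-values equal full assignment enumeration
  (verified for all partitions with nx + ny ≤ 10).
* **Kaplan–Meier / log-rank** (lifelines): product-limit estimator with
  the convention that subjects censored at an event time remain in the
  risk set at that time; the two-group log-rank statistic is
  (ΣO−E)²/ΣV with the hypergeometric variance. Kaplan–Meier curves are
  the survival display; the log-rank test is adopted as their standard
  two-group companion.
* **Gain/loss calls**: Wilcoxon on mutant vs wildtype expression;
  p < α (default 0.05) with a higher/lower mutant median →
  potential gain/loss, otherwise indeterminate; groups under 3 →
  `insufficient_samples`.
* **Drug sensitivity**: per compound, ln(IC50) is standardized to a
  z-score over *all* cell lines in the table (sample SD), and compounds
  are ranked by the median z over the case-matched lines — lower =
  relatively more sensitive. Standardizing per compound makes relative
  sensitivity comparable across compounds with different potency scales;
  comparing matched lines against the full table (rather than unmatched
  lines only) was an open design choice, decided for stability of the
  reference distribution.

## Synthetic cohorts

`generate_cohort` emulates the table formats of public tumor/cell-line
resources — MAF-like mutations, a GISTIC-coded (±2) copy-number matrix so
the copy-number ingestion path is exercised, clinical annotation with
survival, expression, immune markers and IC50 — with planted ground
truth. Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_samples` / `n_planted` | 500 / 10 | cohort size, planted twins |
| `target_match_rate` | 0.8 | planted twins carry ≥ ⌈0.8·T⌉ case alterations |
| `background_alteration_rate` | 0.02 | per-gene Bernoulli for the 200 background genes |
| `case_pickup_rate` | 0.02 | chance a background sample picks up a case alteration |
| TMB | LogNormal(1.2, 0.6) | median ≈ 3.3 mut/Mb, mostly < 10 (MSS-like cohort) |
| confounder | tmb, log-shift 0.6 | planted-group TMB shift; SMD ≈ 0.85 by the lognormal moment formulas |
| `p_mss` | 0.8 | MSS fraction |
| survival | median 730 d, HR 2.0 for planted, censor 1825 d | exponential model |
| expression | N(8, 1), shift +2 in mutant carriers of case genes | 2σ planted effect |
| markers / IC50 | log-normal; planted log-shifts −0.5 / −1.0 | lower marker abundance, higher drug sensitivity in twins |

Background samples are capped at ⌈rate·T⌉ − 1 gene-level case matches, so
at the planted cutoff the DT+ community equals the planted set exactly —
the generator guarantees separability by construction rather than
probabilistically. One integer seed drives all tables through spawned
child generators; identical configs are byte-identical on disk.

What the generator does **not** emulate: mutational signatures,
gene-length-dependent mutation rates, linkage between alterations,
non-exponential survival, realistic marker covariance, and measurement
noise structure in IC50 assays. Passing tests therefore demonstrate that
the *engine* recovers planted structure under its own model; they say
nothing about effect sizes or error rates in real registry data, and the
published mock-up analyses on real resources are not reproduced here.

## Numerical and format choices

Scores are exact rationals realized as floats (n_matched / n_case);
ordering is always tie-broken by id for determinism. Propensity scores
are clipped to (1e-12, 1 − 1e-12) only as a guard; the fallback path is
the real protection against separation. Report JSON is serialized with
sorted keys and no wall-clock timestamp, so fixed seed + fixed inputs →
byte-identical output; provenance carries the inputs, seed and package
version instead. The report schema shipped at
`src/twinmatch/report_schema.json` is generated from the pydantic models
that also validate every load. All on-disk formats are plain TSV/JSON.

Problem sizes in the test-bed runs (cohorts of 80–500 samples, 100-
replicate recovery studies, 1000–2000-replicate null simulations) were
chosen as the smallest sizes at which the tested properties are sharp:
exact recovery is deterministic by construction, and the simulation-based
checks use replicate counts whose binomial noise is well inside the
asserted bands.

## Known limitations

* No gene-symbol alias resolution; mismatched symbol vocabularies
  silently reduce scores.
* The biomarker blend weight in extended matching (w = 0.5) is a
  convention, not an estimate.
* Greedy matching is order-dependent by design; it does not minimize
  total distance.
* The hypergeometric test treats genes as exchangeable; no correction
  for panel composition or gene length.
* Clinical-trial handling is offline table annotation only; no registry
  connectivity.
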