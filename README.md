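# twinmatch

**Digital-twin community construction and comparative analysis from cancer
molecular profiling reports.**

A clinical molecular profiling report (MPR) lists a patient's somatic
alterations in two sets — the *key* (clinically curated) findings and the
*variants of unknown significance* (VUS) — plus report-level biomarkers
(TMB, microsatellite status, PD-L1). `twinmatch` turns that report into a
cohort query: it scores every sample of a tumor or cell-line cohort by how
much of the case's profile it carries, splits the cohort into digital-twin
positive (DT+) and negative (DT−) communities at a score cutoff, balances
the usually much larger DT− community against DT+ by propensity matching,
and runs the downstream comparisons an analyst would ask for — signature
enrichment, chromosome-arm proximity, survival, immune-marker abundance,
gain/loss-of-function, and drug-sensitivity ranking. It is written for
translational researchers and clinical bioinformaticians who want these
analyses scriptable and reproducible rather than point-and-click.

Because real pan-cancer resources (TCGA/CCLE/GDSC-scale) cannot ship with
a package, `twinmatch` includes a synthetic-cohort generator that emulates
their table formats with *planted ground truth* (known twins, a known
confounder, known survival and expression effects), so every analysis
stage is testable end to end with no downloads.

## The score at the core

For a case profile with alteration set $P$ (the *total profile*, key ∪
VUS) and a cohort sample with alteration set $S$, the **connecting score**
is the fraction of the case's alterations present in the sample:

$$\mathrm{score}(P, S) = \frac{\left|\{\,a \in P : \exists\, b \in S,\ a \sim b\,\}\right|}{|P|}$$

where the match relation $a \sim b$ operates at one of three resolutions:
`gene` (same symbol), `gene_alteration` (symbol + alteration class), or
`gene_protein` (symbol + class + protein change; degrades to
`gene_alteration` for non-mutation classes). Samples with score ≥ cutoff
form the DT+ community. "Match the un-matched" then fits a logistic
propensity model of DT+ membership on clinical features (gender, TMB, MS
status, …) and pairs each DT+ sample with its nearest DT− neighbor on the
propensity scale (greedy 1:1, without replacement, optional caliper).
Enrichment uses the upper-tail hypergeometric test with
Benjamini–Hochberg adjustment; survival uses Kaplan–Meier curves with the
log-rank test; group comparisons use the Wilcoxon rank-sum test; drug
sensitivity ranks compounds by the median per-compound z-score of
ln(IC50) over the case-matched cell lines.

## Worked example

Write a four-alteration CRC-flavored case profile, simulate a 500-sample
cohort with 10 planted twins, and run the full pipeline:

```sh
twinmatch simulate --profile case.tsv --seed 7 --out cohort/
twinmatch run-all --profile case.tsv --cohort-dir cohort/ \
    --cutoff 0.8 --balance-features tmb,ms_status --seed 7 --out out/
```

where `case.tsv` is

```text
gene	alteration_class	protein_change	origin
APC	mutation	p.T1556fs	key
KRAS	mutation	p.G12D	key
TP53	mutation	p.R175H	key
PARP2	mutation		vus
```

`out/report.json` from this run contains (abridged):

```text
matching:   DT+ 10 / DT- 490 at cutoff 0.8 (level gene_alteration)
balance:    10 pairs; SMD(tmb) 1.139 -> 0.118 after matching
survival:   log-rank chi2 = 7.48, p = 0.0063 (DT+ vs DT-)
markers:    CD8 median 4.79 (DT+) vs 7.19 (DT-), p = 0.041
gain_loss:  KRAS potential_gain (median 9.97 vs 8.01, p = 8.4e-19)
drugs:      cetuximab rank 1 (median z of ln IC50 = -0.88 in matched lines)
```

Read: the ten samples planted to carry ≥ 80% of the case profile are
recovered exactly as the DT+ community; the planted TMB confounding
(standardized mean difference 1.14 between communities) drops to 0.12
after propensity matching; the planted shorter survival, lower CD8
abundance, mutant over-expression and cetuximab sensitivity of the twin
community are all detected with the expected direction. The companion
TSVs (`scores.tsv`, `communities.tsv`, `comparisons.tsv`, …) carry the
full tables.

The same stages are available as a library (`twinmatch.parse_profile`,
`score_cohort`, `split_communities`, `fit_propensity` /
`match_unmatched`, `enrich_signatures`, `km_estimate`, `logrank_test`,
`gof_lof_call`, `rank_drug_sensitivity`, `generate_cohort`).

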