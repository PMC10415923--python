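"""'Match the un-matched': propensity-score balancing of communities.

The DT+ community is usually far smaller than DT-.  To estimate the effect
of profile matching itself, DT- controls are balanced against DT+ on
MPR-level clinical features (gender, TMB, MS status) via a logistic
propensity model followed by greedy 1:1 nearest-neighbor matching without
replacement.  The same machinery serves mutant-vs-wildtype comparisons for
gain/loss-of-function analyses.

The logistic fit is maximum likelihood (Newton/IRLS, <=100 iterations,
log-likelihood tolerance 1e-8).  When the groups are perfectly separable
the MLE diverges; the fit then falls back to an L2-penalized logistic
regression (penalty 1e-4 on the coefficients, intercept unpenalized) and
``converged`` is flagged False.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BalanceError
from .matching import CohortSample
from .profiles import AlterationClass

logger = logging.getLogger(__name__)

MAX_ITER = 100
LL_TOL = 1e-8
RIDGE_PENALTY = 1e-4
MIN_GROUP = 3


@dataclass(frozen=True)
class PropensityFit:
    coefficients: tuple[float, ...]  # intercept first
    scores: Mapping[str, float]  # sample_id -> P(treated), strictly in (0,1)
    features_used: tuple[str, ...]  # post one-hot encoding column names
    converged: bool
    n_iterations: int


@dataclass(frozen=True)
class MatchedPairs:
    pairs: tuple[tuple[str, str], ...]  # (treated, control)
    caliper: float | None
    unmatched_treated: frozenset[str]


@dataclass(frozen=True)
class GroupSplit:
    """Mutant/wildtype partition, optionally propensity-balanced."""

    gene: str
    mutant: frozenset[str]
    wildtype: frozenset[str]
    excluded: frozenset[str]  # non-mutation carriers of the gene (ambiguous)
    pairs: MatchedPairs | None = None
    refusal: str | None = None


def _design_matrix(
    features_df: pd.DataFrame, features: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Select, one-hot encode, and prune constant columns."""
    missing = [f for f in features if f not in features_df.columns]
    if missing:
        raise BalanceError(f"features absent from clinical data: {missing}")
    X = features_df[list(features)].copy()
    obj_cols = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
    if obj_cols:
        X = pd.get_dummies(X, columns=obj_cols, drop_first=True, dtype=float)
    X = X.astype(float)
    dropped = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if dropped:
        logger.warning("fit_propensity: dropping constant features %s", dropped)
        X = X.drop(columns=dropped)
    return X, list(X.columns)


def fit_propensity(
    features_df: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    features: Sequence[str],
) -> PropensityFit:
    """Logistic regression of treatment label on clinical features.

    ``features_df`` is indexed by sample_id.  Rows with missing values in
    the selected features are dropped with a warning.  An empty feature
    list fits the intercept-only model, whose fitted probability is the
    treated fraction for every sample (MLE score equation).
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    ids = [i for i in features_df.index if i in labels.index]
    if not ids:
        raise BalanceError("no labeled samples found in feature table")
    df = features_df.loc[ids]
    y = labels.loc[ids].astype(float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise BalanceError("labels must contain both treated (1) and control (0) samples")

    if features:
        X, used = _design_matrix(df, features)
        keep = X.notna().all(axis=1)
        if not keep.all():
            logger.warning(
                "fit_propensity: dropping %d samples with missing feature values",
                int((~keep).sum()),
            )
        X, y = X.loc[keep], y.loc[keep]
        if X.shape[1] == 0:
            raise BalanceError("all features dropped (constant or missing)")
        if set(np.unique(y)) != {0.0, 1.0}:
            raise BalanceError("one label class lost after dropping missing rows")
    else:
        X, used = pd.DataFrame(index=df.index), []

    import statsmodels.api as sm

    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    converged = True
    n_iter = 0
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # escalate separation warnings
        try:
            res = sm.Logit(y.to_numpy(), exog).fit(
                method="newton", maxiter=MAX_ITER, tol=LL_TOL, disp=0
            )
            params = np.asarray(res.params, dtype=float)
            n_iter = int(res.mle_retvals.get("iterations", MAX_ITER))
            converged = bool(res.mle_retvals.get("converged", False))
            probs = np.asarray(res.predict(exog), dtype=float)
            if not converged or np.any(probs <= 0) or np.any(probs >= 1):
                raise RuntimeError("non-converged or degenerate fit")
        except Exception:
            params = None

    if params is None:  # separation or non-convergence: ridge-penalized fallback
        logger.warning(
            "fit_propensity: MLE did not converge (likely separation); "
            "falling back to L2-penalized fit (penalty %g)", RIDGE_PENALTY,
        )
        from sklearn.linear_model import LogisticRegression

        if X.shape[1] == 0:
            p = float(y.mean())
            params = np.array([np.log(p / (1 - p))])
            probs = np.full(len(y), p)
            converged, n_iter = True, 1
        else:
            clf = LogisticRegression(
                C=1.0 / RIDGE_PENALTY, solver="lbfgs", max_iter=1000
            )
            clf.fit(X.to_numpy(dtype=float), y.to_numpy())
            params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
            probs = clf.predict_proba(X.to_numpy(dtype=float))[:, 1]
            converged = False
            n_iter = int(getattr(clf, "n_iter_", [MAX_ITER])[0])

    eps = 1e-12
    probs = np.clip(probs, eps, 1 - eps)
    scores = dict(zip(X.index if features else df.index, map(float, probs)))
    return PropensityFit(
        coefficients=tuple(map(float, params)),
        scores=scores,
        features_used=tuple(used),
        converged=converged,
        n_iterations=n_iter,
    )


def match_unmatched(
    fit: PropensityFit,
    labels: Mapping[str, int] | pd.Series,
    caliper: float | None = None,
) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Treated units are processed in descending propensity order (ties by
    sample_id ascending); each takes the unused control with the smallest
    absolute propensity difference (distance ties by control id ascending).
    A pair exceeding the caliper (raw propensity scale) is not formed and
    the treated unit is recorded unmatched.  Deterministic given inputs.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    if caliper is not None and caliper < 0:
        raise BalanceError(f"caliper must be non-negative, got {caliper}")
    treated = [s for s in labels.index if labels[s] == 1 and s in fit.scores]
    controls = [s for s in labels.index if labels[s] == 0 and s in fit.scores]
    if not controls:
        raise BalanceError("no control samples available for matching")
    treated.sort(key=lambda s: (-fit.scores[s], s))
    available = sorted(controls)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for t in treated:
        if not available:
            unmatched.append(t)
            continue
        best = min(available, key=lambda c: (abs(fit.scores[t] - fit.scores[c]), c))
        dist = abs(fit.scores[t] - fit.scores[best])
        if caliper is not None and dist > caliper:
            unmatched.append(t)
            continue
        pairs.append((t, best))
        available.remove(best)
    if unmatched:
        logger.warning("match_unmatched: %d treated units left unmatched", len(unmatched))
    return MatchedPairs(tuple(pairs), caliper, frozenset(unmatched))


def balance_smd(
    group_a: pd.DataFrame, group_b: pd.DataFrame, features: Sequence[str]
) -> dict[str, float]:
    """Standardized mean difference per feature.

    SMD = (mean_A - mean_B) / sqrt((var_A + var_B) / 2) with sample
    variances (ddof=1); 0/0 is defined as 0.  Categorical features must be
    binary-encoded by the caller.
    """
    out: dict[str, float] = {}
    for f in features:
        if f not in group_a.columns or f not in group_b.columns:
            raise BalanceError(f"feature {f!r} absent from one of the groups")
        a = pd.to_numeric(group_a[f], errors="coerce").dropna().to_numpy(dtype=float)
        b = pd.to_numeric(group_b[f], errors="coerce").dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise BalanceError(f"feature {f!r} has no numeric values in one group")
        num = a.mean() - b.mean()
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        denom = np.sqrt((va + vb) / 2.0)
        if denom == 0:
            out[f] = 0.0 if num == 0 else float(np.sign(num) * np.inf)
        else:
            out[f] = float(num / denom)
    return out


def encode_for_smd(features_df: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """One-hot encode categorical columns so SMDs are computable."""
    X = features_df[list(features)].copy()
    obj_cols = [c for c in X.columns if X[c].dtype == object]
    if obj_cols:
        X = pd.get_dummies(X, columns=obj_cols, drop_first=True, dtype=float)
    return X.astype(float)


def mutant_wildtype_groups(
    samples: Sequence[CohortSample],
    gene: str,
    features_for_balance: Sequence[str] | None = None,
    features_df: pd.DataFrame | None = None,
    gene_universe: Iterable[str] = (),
    min_group: int = MIN_GROUP,
) -> GroupSplit:
    """Partition a cohort into mutant and wildtype groups for one gene.

    Mutant = any mutation-class alteration in the gene; wildtype = no
    alteration in the gene at all.  Samples carrying only non-mutation
    alterations of the gene (amplification/deletion/fusion) are excluded
    from both groups — copy-number-only events do not establish the
    mutant genotype.  With fewer than ``min_group`` mutants, matching is
    refused (refusal marker, not an error), mirroring small-n clinical
    practice.
    """
    gene = gene.upper()
    mutant, wildtype, excluded = set(), set(), set()
    seen_gene = gene in {g.upper() for g in gene_universe}
    for s in samples:
        in_gene = [a for a in s.alterations if a.gene == gene]
        if in_gene:
            seen_gene = True
        if any(a.alteration_class is AlterationClass.MUTATION for a in in_gene):
            mutant.add(s.sample_id)
        elif in_gene:
            excluded.add(s.sample_id)
        else:
            wildtype.add(s.sample_id)
    if not seen_gene:
        raise BalanceError(f"gene {gene!r} absent from cohort alteration data and gene universe")
    if excluded:
        logger.info(
            "mutant_wildtype_groups(%s): excluded %d samples with non-mutation "
            "alterations only", gene, len(excluded),
        )
    split = GroupSplit(gene, frozenset(mutant), frozenset(wildtype), frozenset(excluded))
    if len(mutant) < min_group:
        return GroupSplit(
            gene, split.mutant, split.wildtype, split.excluded,
            refusal=f"insufficient mutant samples (n={len(mutant)} < {min_group})",
        )
    if features_for_balance:
        if features_df is None:
            features_df = pd.DataFrame(
                {s.sample_id: dict(s.features) for s in samples}
            ).T
        labels = {s: 1 for s in mutant}
        labels.update({s: 0 for s in wildtype})
        fit = fit_propensity(features_df, labels, features_for_balance)
        pairs = match_unmatched(fit, labels)
        return GroupSplit(gene, split.mutant, split.wildtype, split.excluded, pairs=pairs)
    return split
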