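"""Regularized logistic regression of DE direction on TF affinity quotients,
TF ranking, and the cluster-wise TF effect score.

The regression is nested-CV elastic net (mixing parameter 0.01, i.e.
almost pure ridge): an inner stratified CV picks the penalty strength
over a log grid, outer folds report held-out accuracy, and the final
coefficients come from a fit on all data at the selected penalty.

The effect score for TF t in cluster i is the median log2 affinity
quotient over that cluster's DE genes minus the mean of the medians over
the other clusters, so each TF's scores sum to zero across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    coefficients: pd.Series          # per-TF signed coefficient (final fit)
    normalized_abs: pd.Series        # |coef| / max|coef|, in [0, 1]
    fold_accuracies: list[float]     # outer-fold held-out accuracies
    settings: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class RankedTFs:
    ranking: pd.Series               # normalized |coef| sorted descending
    threshold: float
    selected: list[str]


def _check_stratifiable(y: np.ndarray, n_folds: int, what: str) -> None:
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValidationError(
            f"{what}: smallest class has {counts.min()} members, cannot build "
            f"{n_folds} stratified folds"
        )


def fit_dynamite(quotient: pd.DataFrame, labels: pd.Series, ofolds: int = 10,
                 ifolds: int = 6, alpha: float = 0.01, seed: int = 0,
                 n_penalties: int = 50) -> RegressionResult:
    """Fit the nested-CV elastic-net logistic regression.

    ``quotient`` is a TF x gene matrix; ``labels`` maps each gene to
    "up"/"down".  Features are the per-gene TF quotients, standardized to
    zero mean / unit variance.  ``alpha`` is the elastic-net mixing
    parameter (fraction of L1).
    """
    genes = [g for g in labels.index if g in quotient.columns]
    if len(genes) < len(labels):
        logger.warning("fit_dynamite: %d labeled genes missing from quotient matrix",
                       len(labels) - len(genes))
    x = quotient[genes].to_numpy(dtype=float).T  # genes x TFs
    y = (labels.loc[genes] == "up").to_numpy(dtype=int)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("need >= 2 genes per label")
    _check_stratifiable(y, ofolds, "outer CV")
    _check_stratifiable(y, ifolds, "inner CV")

    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd

    cs = np.logspace(-4, 2, n_penalties)

    def make_clf(cv_seed: int) -> LogisticRegressionCV:
        kwargs = dict(
            Cs=cs, solver="saga", l1_ratios=[alpha],
            cv=StratifiedKFold(ifolds, shuffle=True, random_state=cv_seed),
            max_iter=10_000, tol=1e-4, scoring="accuracy", n_jobs=1,
        )
        try:  # pin pre-1.10 attribute layout while it still warns
            return LogisticRegressionCV(use_legacy_attributes=True, **kwargs)
        except TypeError:
            return LogisticRegressionCV(**kwargs)

    outer = StratifiedKFold(ofolds, shuffle=True, random_state=seed)
    accuracies = []
    for k, (tr, te) in enumerate(outer.split(x, y)):
        clf = make_clf(seed + 1 + k)
        clf.fit(x[tr], y[tr])
        accuracies.append(float(clf.score(x[te], y[te])))

    final = make_clf(seed)
    final.fit(x, y)
    coefs = pd.Series(final.coef_.ravel(), index=quotient.index, name="coefficient")
    max_abs = coefs.abs().max()
    normalized = coefs.abs() / max_abs if max_abs > 0 else coefs.abs() * 0.0
    normalized.name = "normalized_abs_coefficient"
    return RegressionResult(
        coefficients=coefs,
        normalized_abs=normalized,
        fold_accuracies=accuracies,
        settings={"ofolds": ofolds, "ifolds": ifolds, "alpha": alpha, "seed": seed,
                  "C": float(final.C_[0]), "n_penalties": n_penalties},
    )


def rank_tfs(result: RegressionResult, threshold: float = 0.125) -> RankedTFs:
    """Rank TFs by normalized |coefficient|; select those >= ``threshold``.

    Ties sort lexicographically by TF name for deterministic output.
    """
    df = result.normalized_abs.rename("score").reset_index()
    df.columns = ["tf", "score"]
    df = df.sort_values(["score", "tf"], ascending=[False, True])
    ranking = pd.Series(df["score"].to_numpy(), index=df["tf"], name="normalized_abs_coefficient")
    selected = [t for t, s in ranking.items() if s >= threshold]
    return RankedTFs(ranking=ranking, threshold=threshold, selected=selected)


def median_quotient(quotient: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Per-TF median log2 quotient over each cluster's DE genes.

    ``clusters`` maps gene -> cluster index; only genes present in both
    the quotient matrix and the cluster map enter.  Returns a TF x cluster
    DataFrame.  An even gene count yields the mean of the two central
    values (ordinary median).
    """
    cols = {}
    for cl in sorted(clusters.unique()):
        genes = [g for g in clusters.index[clusters == cl] if g in quotient.columns]
        if not genes:
            raise ValidationError(f"cluster {cl} has no genes in the quotient matrix")
        cols[cl] = quotient[genes].median(axis=1)
    return pd.DataFrame(cols)


def effect_score(q: pd.DataFrame, others_divisor: str = "k-1") -> pd.DataFrame:
    """Cluster-wise TF effect score from the median-quotient matrix.

    E[t, i] = Q[t, i] - mean over the other clusters of Q[t, .] when
    ``others_divisor == "k-1"`` (default).  ``"k"`` divides the sum over
    the other clusters by K instead, for sensitivity analysis.
    """
    k = q.shape[1]
    if k < 2:
        raise ConfigurationError("need at least 2 clusters for the effect score")
    if others_divisor not in ("k-1", "k"):
        raise ConfigurationError(f"unknown others_divisor {others_divisor!r}")
    divisor = k - 1 if others_divisor == "k-1" else k
    totals = q.sum(axis=1)
    e = q.subtract((totals.to_numpy()[:, None] - q) / divisor)
    return e


def permutation_null_effect(quotient: pd.DataFrame, clusters: pd.Series,
                            n_perm: int = 200, seed: int = 0) -> np.ndarray:
    """Max |effect score| per permutation of gene->cluster labels (null)."""
    rng = np.random.default_rng(seed)
    values = clusters.to_numpy().copy()
    out = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(values)
        perm = pd.Series(values, index=clusters.index)
        e = effect_score(median_quotient(quotient, perm))
        out[i] = np.abs(e.to_numpy()).max()
    return out
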