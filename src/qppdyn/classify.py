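"""Elastic-net logistic classification of subjects from QPP-derived measures.

Each rsfMRI measure is used alone and all measures jointly in penalised
logistic regressions; performance is the cross-validated ROC AUC, with the
cross-validation repeated to stabilise the estimate, and models are compared
by paired stratified bootstrap of the AUC difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DEFAULT_MEASURES",
    "ClassificationReport",
    "build_measure_table",
    "roc_auc",
    "elastic_net_cv",
    "compare_auc_bootstrap",
    "bonferroni",
]

#: the default 17-measure roster: raw network FC, occurrence rates, network
#: FC after regressing each pattern, and the per-subject FC deltas.
DEFAULT_MEASURES = [
    "FC_DMN", "FC_TPN", "FC_DMN_TPN",
    "rate_QPP_GS", "rate_QPP_WT", "rate_QPP_TG",
    "FC_DMN_after_QPP_WT", "FC_DMN_after_QPP_TG", "FC_DMN_after_QPP_GS",
    "FC_DMN_TPN_after_QPP_WT", "FC_DMN_TPN_after_QPP_TG", "FC_DMN_TPN_after_QPP_GS",
    "dFC_DMN_QPP_WT", "dFC_DMN_QPP_TG", "dFC_DMN_QPP_GS",
    "dFC_DMN_TPN_QPP_WT", "dFC_DMN_TPN_QPP_TG",
]


@dataclass
class ClassificationReport:
    """Per-model AUCs, combined-model coefficients and pairwise comparisons."""

    models: dict = field(default_factory=dict)  # name -> {mean_auc, se_auc, ...}
    betas: pd.DataFrame | None = None  # one row per CV fit, combined model
    comparisons: pd.DataFrame | None = None  # pairwise bootstrap AUC tests

    def to_json_dict(self) -> dict:
        return {
            "models": {
                k: {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                    for kk, vv in v.items() if kk != "oof_scores"}
                for k, v in self.models.items()
            },
            "betas": None if self.betas is None else self.betas.to_dict("list"),
            "comparisons": None if self.comparisons is None
            else self.comparisons.to_dict("list"),
        }


def build_measure_table(measures: dict[str, dict[str, float]], groups: dict[str, str],
                        columns: list[str] | None = None) -> pd.DataFrame:
    """Assemble the subject x measure table.

    ``measures`` maps subject id -> {measure name -> value}; ``groups`` maps
    subject id -> group label.  Raises when a modeled cell is missing.
    """
    columns = list(columns) if columns is not None else list(DEFAULT_MEASURES)
    rows = {}
    for sid in groups:
        if sid not in measures:
            raise ValueError(f"subject {sid!r}: no measures computed")
        row = {}
        for col in columns:
            if col not in measures[sid] or not np.isfinite(measures[sid][col]):
                raise ValueError(f"subject {sid!r}: measure {col!r} missing")
            row[col] = measures[sid][col]
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.insert(0, "group", [groups[s] for s in table.index])
    table.index.name = "subject_id"
    return table


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = labels == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    return (y == classes.max()).astype(int)


def _make_model(l1_ratio, Cs, inner_folds, seed, max_iter):
    if inner_folds < 2:
        # training set too small for inner selection: fixed mid-grid strength
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(
            C=1.0, penalty="elasticnet", solver="saga", l1_ratio=l1_ratio,
            max_iter=max_iter, tol=1e-4, random_state=seed,
        )
    else:
        est = LogisticRegressionCV(
            Cs=Cs, cv=inner_folds, penalty="elasticnet", solver="saga",
            l1_ratios=[l1_ratio], scoring="neg_log_loss",
            max_iter=max_iter, tol=1e-4, random_state=seed,
        )
    return make_pipeline(StandardScaler(), est)


def elastic_net_cv(table: pd.DataFrame, predictors: list[str] | None = None,
                   label_column: str = "group", repeats: int = 10, folds: int = 10,
                   l1_ratio: float = 0.5, Cs=None, inner_folds: int = 5,
                   max_iter: int = 5000, random_state=None) -> dict:
    """Repeated stratified k-fold CV of an elastic-net logistic model.

    Predictors are standardised inside each training fold and the
    regularisation strength is chosen per training fold by inner
    cross-validated log-loss.  Per repeat the AUC is computed from the
    pooled out-of-fold predicted probabilities; coefficients of every fit
    are recorded (``folds x repeats`` rows — 100 at the defaults).
    """
    predictors = list(predictors) if predictors is not None else [
        c for c in table.columns if c != label_column]
    X = table[predictors].to_numpy(dtype=float)
    y = _binary_labels(table[label_column])
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least two subjects per class")
    if Cs is None:
        Cs = np.logspace(-2, 2, 5)
    rng = np.random.default_rng(random_state)

    aucs, betas, oof_mean = [], [], np.zeros(len(y))
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        k = min(folds, len(y), max(2, int(min(np.bincount(y)))))
        while True:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            with warnings.catch_warnings():
                # folds of size 1-2 at small n: stratification is best-effort
                warnings.simplefilter("ignore", UserWarning)
                splits = list(skf.split(X, y))
            if all(np.unique(y[tr]).size == 2 for tr, _ in splits):
                break
            k -= 1  # degenerate training fold: refit with fewer folds
            warnings.warn(f"reducing folds to {k} (single-class training fold)",
                          stacklevel=2)
        oof = np.zeros(len(y))
        for tr, te in splits:
            model = _make_model(l1_ratio, Cs, min(inner_folds, min(np.bincount(y[tr]))),
                                rep_seed, max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            oof[te] = model.predict_proba(X[te])[:, 1]
            betas.append(model[-1].coef_.ravel().copy())
        aucs.append(roc_auc(oof, y))
        oof_mean += oof
    aucs = np.asarray(aucs)
    betas = np.asarray(betas)
    return {
        "predictors": predictors,
        "mean_auc": float(aucs.mean()),
        "se_auc": float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0,
        "aucs": aucs,
        "betas": betas,
        "n_fits": int(betas.shape[0]),
        "oof_scores": oof_mean / repeats,
        "labels": y,
    }


def compare_auc_bootstrap(scores_a, scores_b, labels, n_boot: int = 2000,
                          random_state=None) -> float:
    """Two-sided paired stratified bootstrap test of an AUC difference.

    Subjects are resampled within class (stratified), jointly for both
    models (paired); the observed difference is tested against the normal
    with the bootstrap SD of the difference.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    y = _binary_labels(labels)
    d_obs = roc_auc(scores_a, y) - roc_auc(scores_b, y)
    rng = np.random.default_rng(random_state)
    idx_pos, idx_neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx_pos, idx_pos.size, replace=True),
                               rng.choice(idx_neg, idx_neg.size, replace=True)])
        yy = y[take]
        diffs[b] = roc_auc(scores_a[take], yy) - roc_auc(scores_b[take], yy)
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0 if d_obs == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(d_obs) / sd))


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if m is None:
        m = p.size
    out = np.minimum(1.0, p * m)
    return float(out[0]) if scalar else out
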