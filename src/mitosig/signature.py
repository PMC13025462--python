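"""Bootstrap-LASSO stability selection and the composite diagnostic score.

The discovery procedure this module implements: restrict the feature space
(typically to mitochondria-annotated analytes), then across ``n_iterations``
stratified bootstrap resamples (default 100) fit an L1-penalized logistic
model of tumor subtype (ChRCC = 1 vs ccRCC = 0) on z-scaled log2
intensities, with the penalty chosen per bootstrap by stratified
cross-validation on binomial deviance.  Each bootstrap's out-of-bag (OOB)
samples provide an AUROC / sensitivity / specificity estimate.  Features
whose selection frequency reaches the retention threshold (default 1/3) form
the signature; a full-data penalized refit on the retained features yields
the score formula

    score(sample) = sum_f coef_f * z_f(sample)

whose weights multiply z-scaled expression values (the intercept is not part
of the reported score).

The model object follows the statsmodels convention:
``StabilitySelection(...).fit(...)`` returns a :class:`StabilityResults`
carrying frequencies, per-iteration OOB metrics, the final fit, and
``summary()`` / ``score()`` / ``roc()`` helpers.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _l1
from .dataset import ExpressionDataset, DatasetError

__all__ = [
    "ScalingParams",
    "L1LogisticFit",
    "standardize",
    "fit_l1_logistic",
    "select_lambda_cv",
    "StabilitySelection",
    "StabilityResults",
    "bootstrap_stability",
    "compute_score",
    "auroc",
    "roc_curve",
    "RocCurve",
    "multivariable_logistic",
    "subset_sensitivity",
]


# ---------------------------------------------------------------------------
# scaling


@dataclasses.dataclass
class ScalingParams:
    """Per-feature mean/SD (ddof=1) estimated on a fitting set."""

    features: list
    mean: np.ndarray
    sd: np.ndarray
    dropped_zero_var: list

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = X.loc[:, self.features]
        return (Z - self.mean) / self.sd

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z.loc[:, self.features] * self.sd + self.mean

    def to_dict(self):
        return {
            "features": [str(f) for f in self.features],
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
            "dropped_zero_var": [str(f) for f in self.dropped_zero_var],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(list(d["features"]), np.asarray(d["mean"], float),
                   np.asarray(d["sd"], float), list(d["dropped_zero_var"]))


def standardize(X: pd.DataFrame):
    """Z-scale each feature to mean 0, SD 1 (ddof=1) on the fitting set.

    Zero-variance features are excluded and reported via
    ``ScalingParams.dropped_zero_var``.  Returns ``(scaled, params)``.
    """
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(X.columns[~keep])
    params = ScalingParams(
        features=list(X.columns[keep]),
        mean=mean[keep].to_numpy(),
        sd=sd[keep].to_numpy(),
        dropped_zero_var=dropped,
    )
    return params.transform(X), params


# ---------------------------------------------------------------------------
# L1 logistic


@dataclasses.dataclass
class L1LogisticFit:
    """Solution of the L1-penalized logistic objective at one penalty."""

    lambda_: float
    intercept: float
    coef: pd.Series  # per-feature, mostly zero
    converged: bool
    n_iter: int

    @property
    def selected(self):
        return list(self.coef.index[self.coef.to_numpy() != 0.0])

    def predict_proba(self, Z: pd.DataFrame) -> np.ndarray:
        eta = self.intercept + Z.loc[:, self.coef.index].to_numpy() @ self.coef.to_numpy()
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def fit_l1_logistic(X_scaled, y, lambda_, tol=1e-10, max_outer=100) -> L1LogisticFit:
    """Fit L1-penalized logistic regression by coordinate descent.

    ``X_scaled`` should be z-scaled (any DataFrame/array accepted); ``y`` is
    0/1 with both classes present.  The returned solution satisfies the KKT
    stationarity conditions within solver tolerance; non-convergence at the
    iteration cap is flagged on the result, not silent.
    """
    X_df = _as_frame(X_scaled)
    y = np.asarray(y, dtype=float)
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    _l1._check_binary(y)
    lam_seq = np.array([float(lambda_)])
    betas, b0s, iters, convs = _l1.l1_logistic_path(
        X_df.to_numpy(), y, lam_seq, tol=tol, max_outer=max_outer)
    fit = L1LogisticFit(
        lambda_=float(lambda_), intercept=float(b0s[0]),
        coef=pd.Series(betas[0], index=X_df.columns),
        converged=bool(convs[0]), n_iter=int(iters[0]),
    )
    if not fit.converged:
        warnings.warn("L1 logistic solver hit the iteration cap before "
                      "converging", RuntimeWarning, stacklevel=2)
    return fit


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _binomial_deviance(y, prob):
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _stratified_folds(y, k, rng, groups=None):
    """Deterministic stratified k-fold assignment from a Generator.

    With ``groups`` (e.g. source-sample ids of a bootstrap resample) all
    rows of a group share a fold, so duplicated samples can never sit in
    both a training and its validation fold.
    """
    y = np.asarray(y)
    if groups is None:
        fold = np.empty(len(y), dtype=np.int64)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = idx[rng.permutation(len(idx))]
            fold[idx] = np.arange(len(idx)) % k
        return fold
    groups = np.asarray(groups)
    fold_of = {}
    for cls in (0, 1):
        uniq = np.unique(groups[y == cls])
        uniq = uniq[rng.permutation(len(uniq))]
        for i, g in enumerate(uniq):
            fold_of[g] = i % k
    return np.array([fold_of[g] for g in groups], dtype=np.int64)


def make_lambda_grid(X_scaled, y, n_lambda=25, decades=2.0):
    """Log-spaced penalty grid from lambda_max down ``decades`` decades."""
    lmax = _l1.lambda_max(np.asarray(X_scaled, float), np.asarray(y, float))
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)


def select_lambda_cv(X_scaled, y, k=5, lambda_grid=None, rng=None, n_lambda=15,
                     rule="1se", groups=None):
    """Choose the penalty by cross-validated held-out binomial deviance.

    Stratified ``k``-fold CV over a decreasing log-spaced grid (default:
    2 decades down from the analytic lambda_max), warm-started along the
    path within each fold.  ``rule="min"`` takes the deviance-minimizing
    penalty (ties resolve to the largest penalty attaining the minimum);
    the default ``rule="1se"`` takes the largest penalty whose mean deviance
    is within one standard error of the minimum -- the usual conservative
    convention, which keeps spurious cohort-level correlations from
    dragging the penalty to the bottom of the grid on null data.
    Returns ``(lambda, grid, mean_deviance)``.
    """
    X_df = _as_frame(X_scaled)
    X = np.ascontiguousarray(X_df.to_numpy(), dtype=float)
    y = np.asarray(y, dtype=float)
    _l1._check_binary(y)
    minority = int(min((y == 0).sum(), (y == 1).sum()))
    if k > minority:
        raise ValueError(f"k={k} folds exceed the minority class count {minority}")
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(X, y, n_lambda=n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    if len(lambda_grid) == 1:
        return float(lambda_grid[0]), lambda_grid, np.array([np.nan])
    if rng is None:
        rng = np.random.default_rng(0)
    fold = _stratified_folds(y, k, rng, groups=groups)
    dev = np.full((k, len(lambda_grid)), np.nan)
    for f in range(k):
        tr = fold != f
        te = ~tr
        if te.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        betas, b0s, _, _ = _l1.l1_logistic_path(X[tr], y[tr], lambda_grid,
                                                tol=1e-8)
        eta = b0s[None, :] + X[te] @ betas.T  # (n_te, n_lambda)
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        prob = np.clip(prob, 1e-12, 1 - 1e-12)
        yt = y[te][:, None]
        dev[f] = -2.0 * np.mean(yt * np.log(prob) + (1 - yt) * np.log(1 - prob), axis=0)
    if np.all(np.isnan(dev)):
        raise ValueError("no usable CV fold (each training split single-class)")
    mean_dev = np.nanmean(dev, axis=0)
    best = int(np.nanargmin(mean_dev))  # first index = largest lambda on ties
    if rule == "min":
        chosen = best
    elif rule == "1se":
        col = dev[:, best]
        col = col[np.isfinite(col)]
        se = float(col.std(ddof=1)) / np.sqrt(len(col)) if len(col) > 1 else 0.0
        within = np.flatnonzero(mean_dev <= mean_dev[best] + se)
        chosen = int(within[0])  # largest penalty inside the band
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return float(lambda_grid[chosen]), lambda_grid, mean_dev


# ---------------------------------------------------------------------------
# AUROC / ROC


def auroc(scores, labels):
    """Mann-Whitney AUROC: P(random positive outscores random negative).

    Ties count 1/2.  ``labels`` is 0/1; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclasses.dataclass
class RocCurve:
    """Stepwise ROC curve; monotone in both coordinates, (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self):
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})

    def plot(self, ax=None, label=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lab = label or f"AUC = {self.auc:.3f}"
        ax.plot(self.fpr, self.tpr, drawstyle="steps-post", label=lab)
        ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def roc_curve(scores, labels) -> RocCurve:
    """ROC over all distinct thresholds; trapezoidal area equals :func:`auroc`."""
    from sklearn import metrics

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=area)


# ---------------------------------------------------------------------------
# score


def compute_score(X_log2: pd.DataFrame, score_formula: Mapping[str, float],
                  scaling: ScalingParams) -> pd.Series:
    """Composite diagnostic score: sum of coefficient x z-scaled intensity.

    The intercept is deliberately excluded -- the reported score is the
    weighted sum of scaled expression values only.
    """
    features = list(score_formula.keys())
    missing = [f for f in features if f not in X_log2.columns]
    if missing:
        raise KeyError(f"features absent from the matrix: {missing}")
    missing = [f for f in features if f not in scaling.features]
    if missing:
        raise KeyError(f"features without scaling parameters: {missing}")
    pos = [scaling.features.index(f) for f in features]
    z = (X_log2.loc[:, features].to_numpy() - scaling.mean[pos]) / scaling.sd[pos]
    coefs = np.array([score_formula[f] for f in features], dtype=float)
    return pd.Series(z @ coefs, index=X_log2.index, name="score")


# ---------------------------------------------------------------------------
# stability selection


class StabilitySelection:
    """Bootstrap-LASSO stability selection model for a binary contrast.

    Parameters
    ----------
    X : pandas.DataFrame
        Samples x features matrix of log2 intensities.
    y : array-like of 0/1
        Class labels (1 = positive class, here ChRCC).
    """

    def __init__(self, X: pd.DataFrame, y):
        self.X = _as_frame(X)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y disagree on the number of samples")
        _l1._check_binary(self.y)

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset, positive="ChRCC",
                     restrict_mito=True):
        """Build from a log2 :class:`ExpressionDataset` using the subtype label."""
        if dataset.scale != "log2":
            raise DatasetError("stability selection expects log2 intensities")
        if restrict_mito:
            dataset = dataset.restrict_to_flag("is_mitochondrial")
        y = (dataset.samples["subtype"] == positive).astype(float).to_numpy()
        return cls(dataset.rfu, y)

    def fit(self, n_iterations=100, threshold=1 / 3, seed=0, cv_folds=5,
            n_lambda=15, lambda_rule="1se") -> "StabilityResults":
        """Run the bootstrap, retain stable features, refit the final model.

        Per iteration: class-stratified bootstrap of the full sample size,
        z-scaling on the bootstrap, CV-selected penalty, L1 fit, OOB
        evaluation with the training scaling.  Fully reproducible given
        ``seed`` (one master seed spawns per-iteration substreams, so earlier
        iterations are unchanged when ``n_iterations`` grows).
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        X, y = self.X, self.y
        n = len(y)
        case_idx = np.flatnonzero(y == 1)
        ctrl_idx = np.flatnonzero(y == 0)
        master = np.random.SeedSequence(seed)
        children = master.spawn(n_iterations + 1)

        counts = pd.Series(0.0, index=X.columns)
        records = []
        for it in range(n_iterations):
            rng = np.random.default_rng(children[it])
            boot = np.concatenate([
                rng.choice(case_idx, size=len(case_idx), replace=True),
                rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
            ])
            oob = np.setdiff1d(np.arange(n), np.unique(boot))
            Xb = X.iloc[boot]
            yb = y[boot]
            Zb, scaling = standardize(Xb)
            lam, grid, _ = select_lambda_cv(Zb, yb, k=cv_folds, rng=rng,
                                            n_lambda=n_lambda, rule=lambda_rule,
                                            groups=boot)
            fit = _path_fit(Zb, yb, lam, grid)
            selected = fit.selected
            counts[selected] += 1.0

            rec = {
                "iteration": it,
                "lambda": lam,
                "n_selected": len(selected),
                "n_oob": len(oob),
                "oob_auroc": np.nan,
                "oob_sensitivity": np.nan,
                "oob_specificity": np.nan,
                "single_class_oob": False,
                "selected_features": selected,
            }
            if len(oob) > 0:
                Zo = scaling.transform(X.iloc[oob])
                prob = fit.predict_proba(Zo)
                yo = y[oob]
                pred = prob >= 0.5
                if (yo == 1).any():
                    rec["oob_sensitivity"] = float(pred[yo == 1].mean())
                if (yo == 0).any():
                    rec["oob_specificity"] = float((~pred[yo == 0]).mean())
                if (yo == 1).any() and (yo == 0).any():
                    rec["oob_auroc"] = auroc(prob, yo)
                else:
                    rec["single_class_oob"] = True
            records.append(rec)

        iterations = pd.DataFrame.from_records(records).set_index("iteration")
        frequency = counts / n_iterations
        retained = list(frequency.index[frequency.to_numpy() >= threshold])

        final_fit = None
        scaling_full = None
        score_formula = {}
        if retained:
            Zf, scaling_full = standardize(X.loc[:, retained])
            rng_final = np.random.default_rng(children[n_iterations])
            lam_f, grid_f, _ = select_lambda_cv(Zf, y, k=cv_folds, rng=rng_final,
                                                n_lambda=n_lambda, rule=lambda_rule)
            final_fit = _path_fit(Zf, y, lam_f, grid_f)
            score_formula = {str(f): float(c) for f, c in final_fit.coef.items()}

        return StabilityResults(
            model=self,
            n_iterations=n_iterations,
            threshold=float(threshold),
            seed=int(seed),
            selection_frequency=frequency,
            retained_features=retained,
            iterations=iterations,
            final_fit=final_fit,
            scaling=scaling_full,
            score_formula=score_formula,
        )


def _path_fit(Z: pd.DataFrame, y, lam, grid) -> L1LogisticFit:
    """Fit at ``lam`` by warm-starting down the path from lambda_max."""
    sub = np.asarray(grid, float)
    sub = np.sort(sub[sub >= lam * (1 - 1e-12)])[::-1]
    if len(sub) == 0 or abs(sub[-1] - lam) > 1e-12 * max(lam, 1.0):
        sub = np.append(sub, lam)
    betas, b0s, iters, convs = _l1.l1_logistic_path(Z.to_numpy(), y, sub)
    return L1LogisticFit(
        lambda_=float(lam), intercept=float(b0s[-1]),
        coef=pd.Series(betas[-1], index=Z.columns),
        converged=bool(convs[-1]), n_iter=int(iters.sum()),
    )


class StabilityResults:
    """Results of :meth:`StabilitySelection.fit`.

    Attributes include per-feature ``selection_frequency``, the
    ``retained_features`` (frequency >= threshold), the per-iteration OOB
    metric table ``iterations`` (AUROC is NaN for iterations whose OOB set
    lacks a class; those are tallied in ``n_single_class_oob``), and the
    full-data ``final_fit`` restricted to retained features together with the
    ``score_formula`` mapping feature -> coefficient.
    """

    def __init__(self, model, n_iterations, threshold, seed, selection_frequency,
                 retained_features, iterations, final_fit, scaling, score_formula):
        self.model = model
        self.n_iterations = n_iterations
        self.threshold = threshold
        self.seed = seed
        self.selection_frequency = selection_frequency
        self.retained_features = retained_features
        self.iterations = iterations
        self.final_fit = final_fit
        self.scaling = scaling
        self.score_formula = score_formula

    # -- summaries ----------------------------------------------------------

    @property
    def no_stable_features(self):
        return len(self.retained_features) == 0

    @property
    def n_single_class_oob(self):
        return int(self.iterations["single_class_oob"].sum())

    @property
    def mean_oob_auroc(self):
        return float(self.iterations["oob_auroc"].mean())

    @property
    def median_oob_auroc(self):
        return float(self.iterations["oob_auroc"].median())

    @property
    def median_oob_sensitivity(self):
        return float(self.iterations["oob_sensitivity"].median())

    @property
    def median_oob_specificity(self):
        return float(self.iterations["oob_specificity"].median())

    def score(self, X_log2=None) -> pd.Series:
        """Composite score for the given matrix (default: the fitting data)."""
        if self.no_stable_features:
            raise ValueError("no stable features were retained; no score defined")
        if X_log2 is None:
            X_log2 = self.model.X
        return compute_score(X_log2, self.score_formula, self.scaling)

    @property
    def full_auroc(self):
        """AUROC of the final score on the full fitting cohort."""
        return auroc(self.score(), self.model.y)

    def roc(self, X_log2=None, y=None) -> RocCurve:
        if y is None:
            y = self.model.y
        return roc_curve(self.score(X_log2), y)

    def summary(self) -> str:
        lines = [
            "Bootstrap-LASSO stability selection",
            "===================================",
            f"iterations:            {self.n_iterations}",
            f"retention threshold:   {self.threshold:.3f}",
            f"seed:                  {self.seed}",
            f"features considered:   {self.model.X.shape[1]}",
            f"retained features:     {len(self.retained_features)}",
        ]
        if self.no_stable_features:
            lines.append("NOTE: no stable features (empty retained set)")
        else:
            for f in self.retained_features:
                lines.append(
                    f"  {f}: frequency {self.selection_frequency[f]:.2f}, "
                    f"coefficient {self.score_formula.get(str(f), 0.0):+.4f}"
                )
            terms = " + ".join(
                f"{f} x {c:.3f}" for f, c in self.score_formula.items() if c != 0.0
            )
            lines.append(f"score = {terms if terms else '0'}")
            lines.append(f"full-cohort AUROC:     {self.full_auroc:.3f}")
        lines += [
            f"mean OOB AUROC:        {self.mean_oob_auroc:.3f}",
            f"median OOB AUROC:      {self.median_oob_auroc:.3f}",
            f"median OOB sens/spec:  {self.median_oob_sensitivity:.2f} / "
            f"{self.median_oob_specificity:.2f}",
            f"single-class OOB sets: {self.n_single_class_oob}",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        it = self.iterations.drop(columns=["selected_features"]).copy()
        return {
            "n_iterations": self.n_iterations,
            "threshold": self.threshold,
            "seed": self.seed,
            "selection_frequency": {str(k): float(v)
                                    for k, v in self.selection_frequency.items()},
            "retained_features": [str(f) for f in self.retained_features],
            "no_stable_features": self.no_stable_features,
            "score_formula": self.score_formula,
            "final_intercept": (None if self.final_fit is None
                                else float(self.final_fit.intercept)),
            "final_lambda": (None if self.final_fit is None
                             else float(self.final_fit.lambda_)),
            "scaling": None if self.scaling is None else self.scaling.to_dict(),
            "mean_oob_auroc": _none_if_nan(self.mean_oob_auroc),
            "median_oob_auroc": _none_if_nan(self.median_oob_auroc),
            "median_oob_sensitivity": _none_if_nan(self.median_oob_sensitivity),
            "median_oob_specificity": _none_if_nan(self.median_oob_specificity),
            "n_single_class_oob": self.n_single_class_oob,
            "iterations": json.loads(it.to_json(orient="records")),
        }

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _none_if_nan(x):
    return None if (x is None or (isinstance(x, float) and np.isnan(x))) else float(x)


def bootstrap_stability(X_log2, y, n_iterations=100, threshold=1 / 3, seed=0,
                        **kwargs) -> StabilityResults:
    """Functional wrapper around :class:`StabilitySelection`."""
    return StabilitySelection(X_log2, y).fit(
        n_iterations=n_iterations, threshold=threshold, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# multivariable adjustment and subset sensitivity


def multivariable_logistic(score, covariates: pd.DataFrame, y) -> pd.DataFrame:
    """Unpenalized logistic fit of y on score + clinical covariates.

    Categorical covariates are dummy-coded (first level dropped); booleans
    become 0/1 indicators; ``score=None`` fits covariates (or the intercept)
    alone.  Returns one row per term with the odds ratio,
    Wald 95% CI on the exponentiated scale and the Wald p-value.  Detected
    separation (diverging coefficients) is flagged with a warning while the
    iteration count stays capped.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    index = covariates.index if len(covariates) else pd.RangeIndex(len(y))
    design = pd.DataFrame(index=index)
    if score is not None:
        design["score"] = np.asarray(score, dtype=float)
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == bool or set(s.dropna().unique()) <= {0, 1, True, False}:
            design[col] = s.astype(float).to_numpy()
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            for dcol in dummies.columns:
                design[dcol] = dummies[dcol].astype(float).to_numpy()
    exog = sm.add_constant(design.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, exog).fit(method="newton", maxiter=100, disp=0)
    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    if np.any(np.abs(params[1:]) > 15) or not np.all(np.isfinite(se)):
        warnings.warn("possible separation: coefficients diverging; estimates "
                      "reported at the iteration cap", RuntimeWarning, stacklevel=2)
    zq = stats.norm.ppf(0.975)
    names = ["intercept"] + list(design.columns)
    out = pd.DataFrame({
        "term": names,
        "odds_ratio": np.exp(params),
        "ci95_low": np.exp(params - zq * se),
        "ci95_high": np.exp(params + zq * se),
        "wald_p": 2 * stats.norm.sf(np.abs(params / se)),
    }).set_index("term")
    return out


def subset_sensitivity(dataset: ExpressionDataset, results: StabilityResults,
                       subsets: Mapping[str, Sequence[bool]] | None = None,
                       positive="ChRCC"):
    """Evaluate the frozen full-cohort score in clinical subsets.

    ``subsets`` maps name -> boolean mask over the dataset's samples; the
    default evaluates the metastatic-only and treatment-naive subsets.  The
    score uses the full-cohort formula and scaling (nothing is refitted).
    Subsets lacking a class are skipped and reported in the returned
    ``skipped`` list.  Returns ``(table, curves, skipped)``.
    """
    if dataset.scale != "log2":
        raise DatasetError("subset sensitivity expects log2 intensities")
    if subsets is None:
        subsets = {
            "metastatic_only": dataset.samples["metastatic"].astype(bool).to_numpy(),
            "treatment_naive": ~dataset.samples["prior_therapy"].astype(bool).to_numpy(),
        }
    scores = compute_score(dataset.rfu, results.score_formula, results.scaling)
    y_all = (dataset.samples["subtype"] == positive).astype(int).to_numpy()
    rows, curves, skipped = [], {}, []
    for name, mask in subsets.items():
        mask = np.asarray(mask, dtype=bool)
        y_sub = y_all[mask]
        if len(np.unique(y_sub)) < 2:
            skipped.append(name)
            continue
        s_sub = scores.to_numpy()[mask]
        curve = roc_curve(s_sub, y_sub)
        curves[name] = curve
        rows.append({"subset": name, "n": int(mask.sum()),
                     "n_positive": int(y_sub.sum()), "auroc": curve.auc})
    table = pd.DataFrame(rows).set_index("subset") if rows else pd.DataFrame(
        columns=["n", "n_positive", "auroc"])
    return table, curves, skipped
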