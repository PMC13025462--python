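"""Per-analyte differential expression with empirical-Bayes moderation.

Each analyte's log2 intensity is modelled by a two-group linear model
(intercept + subtype indicator), so the coefficient of interest is the
ChRCC-minus-ccRCC mean difference on the log2 scale (log2 fold change) and
the residual variance has n - 2 degrees of freedom.  The per-analyte
variances s_g^2 are then shrunk toward an ensemble prior: assuming

    s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_df / df,
    1 / sigma_g^2     ~ chi^2_d0 / (d0 * s0^2)     (scaled inverse chi-square)

the marginal of log s_g^2 is a shifted log-F, whose first two moments give
closed-form estimators of the hyperparameters (d0, s0^2) via digamma /
trigamma inversion.  The posterior variance

    s~_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

yields the moderated t statistic t_g = log2FC_g / (s~_g * sqrt(1/n1 + 1/n2))
referred to a t distribution with d0 + df degrees of freedom.  d0 = 0
recovers the ordinary two-sample t; d0 = infinity pools all variances at
s0^2.

Calls: |log2FC| >= 1 and Benjamini-Hochberg q <= 0.05 (up/down/ns).
A paired Wilcoxon signed-rank comparison for the tissue cohort
(tumor vs matched normal) is also provided.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset, DatasetError

__all__ = [
    "EBayesPrior",
    "fit_linear_models",
    "ebayes_moderate",
    "bh_adjust",
    "call_differential",
    "paired_wilcoxon",
    "ModeratedTTest",
    "ModeratedTTestResults",
]


@dataclasses.dataclass
class EBayesPrior:
    """Moderation hyperparameters: prior df d0 (may be inf) and prior variance s0^2."""

    d0: float
    s0_sq: float


def fit_linear_models(dataset: ExpressionDataset, contrast: str = "subtype",
                      case: str = "ChRCC", control: str = "ccRCC") -> pd.DataFrame:
    """Two-group linear model per analyte on log2 intensities.

    Returns a DataFrame indexed by SeqId with ``log2fc`` (case minus
    control group mean), ``avg_expr``, pooled residual variance
    ``sigma_sq`` and ``df_resid`` = n - 2.
    """
    if dataset.scale != "log2":
        raise DatasetError("fit_linear_models expects log2 intensities")
    groups = dataset.samples[contrast]
    mask_case = (groups == case).to_numpy()
    mask_ctrl = (groups == control).to_numpy()
    n1, n2 = int(mask_case.sum()), int(mask_ctrl.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {case}: {n1}, {control}: {n2})")
    X = dataset.rfu.to_numpy()
    xc, xk = X[mask_case], X[mask_ctrl]
    mc, mk = xc.mean(axis=0), xk.mean(axis=0)
    ss = ((xc - mc) ** 2).sum(axis=0) + ((xk - mk) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    out = pd.DataFrame(
        {
            "gene_symbol": dataset.analytes["gene_symbol"].to_numpy(),
            "log2fc": mc - mk,
            "avg_expr": X[mask_case | mask_ctrl].mean(axis=0),
            "sigma_sq": ss / df,
            "df_resid": float(df),
        },
        index=dataset.rfu.columns,
    )
    out.attrs["n_case"] = n1
    out.attrs["n_control"] = n2
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone map)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sigma_sq: np.ndarray, df: float) -> EBayesPrior:
    """Moment-matching estimate of (d0, s0^2) from an ensemble of variances.

    Works on e_g = log s_g^2 - digamma(df/2) + log(df/2), whose mean is
    log s0^2 + digamma(d0/2) - log(d0/2) and whose variance is
    trigamma(df/2) + trigamma(d0/2).
    """
    s2 = np.asarray(sigma_sq, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    evar_excess = evar - float(special.polygamma(1, df / 2.0))
    if evar_excess > 0:
        d0 = 2.0 * _trigamma_inverse(evar_excess)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return EBayesPrior(d0=float(d0), s0_sq=s0_sq)


def ebayes_moderate(fits: pd.DataFrame, prior_d0: float | None = None,
                    prior_s0_sq: float | None = None):
    """Empirical-Bayes variance moderation of per-analyte linear fits.

    Parameters
    ----------
    fits : DataFrame
        Output of :func:`fit_linear_models` (needs >= 10 analytes unless the
        prior is supplied); its attrs carry the group sizes.
    prior_d0, prior_s0_sq : float, optional
        Override the estimated hyperparameters (d0 = 0 gives the ordinary t,
        d0 = inf full shrinkage to s0^2).

    Returns
    -------
    (EBayesPrior, DataFrame)
        The prior and a copy of ``fits`` with ``s_tilde_sq``, ``t_mod``, ``p``.
    """
    df = float(fits["df_resid"].iloc[0])
    s2 = fits["sigma_sq"].to_numpy()
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero: degenerate ensemble")
    if prior_d0 is None:
        if len(fits) < 10:
            raise ValueError("hyperparameter estimation needs >= 10 analytes")
        prior = estimate_prior(s2, df)
        if prior_s0_sq is not None:
            prior.s0_sq = float(prior_s0_sq)
    else:
        d0 = float(prior_d0)
        if prior_s0_sq is None and d0 > 0:
            prior_s0_sq = estimate_prior(s2, df).s0_sq
        prior = EBayesPrior(d0=d0, s0_sq=float(prior_s0_sq) if prior_s0_sq else 1.0)

    d0, s0 = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 == 0:
        s_tilde_sq = s2.copy()
        df_total = df
    else:
        s_tilde_sq = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    n1, n2 = fits.attrs["n_case"], fits.attrs["n_control"]
    se_scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits["log2fc"].to_numpy() / (np.sqrt(s_tilde_sq) * se_scale)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = fits.copy()
    out["s_tilde_sq"] = s_tilde_sq
    out["t_mod"] = t_mod
    out["p"] = p
    out.attrs.update(fits.attrs)
    return prior, out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(rows: pd.DataFrame, lfc_thresh: float = 1.0,
                      fdr_thresh: float = 0.05) -> pd.DataFrame:
    """Assign up / down / ns calls from log2fc and BH q thresholds."""
    out = rows.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    call = np.full(len(out), "ns", dtype=object)
    sig = out["q"].to_numpy() <= fdr_thresh
    lfc = out["log2fc"].to_numpy()
    call[sig & (lfc >= lfc_thresh)] = "up"
    call[sig & (lfc <= -lfc_thresh)] = "down"
    out["call"] = call
    out.attrs.update(rows.attrs)
    return out


def paired_wilcoxon(values_a, values_b):
    """Wilcoxon signed-rank test for paired measurements.

    Zero differences are discarded; the remaining n must be >= 5.  The
    two-sided p is exact for n <= 25 (sign-flip distribution of the
    midrank sum, valid with tied magnitudes) and a normal approximation
    with continuity correction above.  Returns ``(W_plus, p_two_sided)``
    where W_plus is the rank sum of positive differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    if len(d) < 5:
        raise ValueError("need >= 5 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if len(d) <= 25:
        return w_plus, _signflip_exact_p(ranks, w_plus)
    res = stats.wilcoxon(d, zero_method="wilcox", method="approx",
                         correction=True)
    return w_plus, float(res.pvalue)


def _signflip_exact_p(ranks, w_plus):
    """Exact two-sided p of the signed-rank sum over all 2^n sign flips.

    Midranks are doubled to integers and the distribution of the positive-
    rank sum is built by subset-sum convolution; the null is symmetric
    about half the total, so the two-sided p is the symmetric tail mass.
    """
    doubled = np.rint(2 * np.asarray(ranks)).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for v in doubled:
        counts[v:] += counts[:-v] if v > 0 else counts
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    dev = abs(w2 - total / 2)
    support = np.arange(total + 1)
    return float(counts[np.abs(support - total / 2) >= dev - 1e-9].sum())


# ---------------------------------------------------------------------------
# model / results


class ModeratedTTest:
    """Moderated two-group differential-expression model.

    Parameters
    ----------
    dataset : ExpressionDataset
        log2-scale dataset with subtype labels.
    lfc_threshold, fdr_threshold : float
        Call thresholds (|log2FC| >= 1, q <= 0.05 by default).
    """

    def __init__(self, dataset: ExpressionDataset, contrast: str = "subtype",
                 case: str = "ChRCC", control: str = "ccRCC",
                 lfc_threshold: float = 1.0, fdr_threshold: float = 0.05):
        self.dataset = dataset
        self.contrast = contrast
        self.case = case
        self.control = control
        self.lfc_threshold = lfc_threshold
        self.fdr_threshold = fdr_threshold

    def fit(self, prior_d0: float | None = None,
            prior_s0_sq: float | None = None) -> "ModeratedTTestResults":
        fits = fit_linear_models(self.dataset, self.contrast, self.case, self.control)
        prior, moderated = ebayes_moderate(fits, prior_d0=prior_d0,
                                           prior_s0_sq=prior_s0_sq)
        moderated["q"] = bh_adjust(moderated["p"].to_numpy())
        table = call_differential(moderated, self.lfc_threshold, self.fdr_threshold)
        return ModeratedTTestResults(self, prior, table)


class ModeratedTTestResults:
    """Per-analyte moderated-t table plus the shared prior."""

    def __init__(self, model: ModeratedTTest, prior: EBayesPrior, table: pd.DataFrame):
        self.model = model
        self.prior = prior
        self.table = table

    @property
    def n_up(self):
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self):
        return int((self.table["call"] == "down").sum())

    def top(self, n=12, direction="up"):
        sub = self.table[self.table["call"] == direction]
        return sub.sort_values("q").head(n)

    def upregulated_genes(self):
        """Unique gene symbols with >= 1 analyte called up (for enrichment)."""
        sub = self.table[(self.table["call"] == "up")
                         & (self.table["gene_symbol"].astype(str) != "")]
        return sorted(set(sub["gene_symbol"].astype(str).str.upper()))

    def universe_genes(self):
        """All unique non-empty gene symbols on the panel."""
        g = self.table["gene_symbol"].astype(str)
        return sorted(set(g[g != ""].str.upper()))

    def summary(self) -> str:
        d0 = "inf" if np.isinf(self.prior.d0) else f"{self.prior.d0:.2f}"
        return "\n".join([
            "Moderated differential expression (ChRCC vs ccRCC)",
            "==================================================",
            f"analytes tested:      {len(self.table)}",
            f"prior df d0:          {d0}",
            f"prior variance s0^2:  {self.prior.s0_sq:.4f}",
            f"call thresholds:      |log2FC| >= {self.model.lfc_threshold}, "
            f"q <= {self.model.fdr_threshold}",
            f"upregulated:          {self.n_up}",
            f"downregulated:        {self.n_down}",
        ])

    def to_tsv(self, path):
        cols = ["gene_symbol", "log2fc", "avg_expr", "t_mod", "p", "q", "call"]
        out = self.table[cols].copy()
        out.index.name = "seq_id"
        out.to_csv(path, sep="\t", float_format="%.6g")
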