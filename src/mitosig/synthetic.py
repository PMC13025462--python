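"""Synthetic cohort generator mirroring the study's data structure.

The generator emulates a plasma aptamer-proteomics case-control cohort:
18 chromophobe (ChRCC) cases vs 197 clear-cell (ccRCC) controls measured on
a large analyte panel, a subset of analytes flagged as mitochondrial, a
handful of planted upregulated analytes with log2 fold changes in the
2.5-3.8 range (mostly mitochondrial), three planted downregulated analytes
at -2.5 / -1.2 / -1.0, log-normal RFU (Gaussian on the log2 scale) with
unit within-group SD, clinical covariates drawn with the study cohort's
marginal frequencies, and overall survival whose hazard is exponential in
the standardized true signature score.

Every generator is a pure function of its spec + seed; ground truth is
returned alongside the data for recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, BridgingTable, DatasetError
from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "attach_survival",
    "generate_paired_tissue",
    "generate_bridging_fixture",
    "generate_gene_sets",
    "CHRCC_MARGINALS",
    "CCRCC_MARGINALS",
]

# Marginal covariate frequencies of the discovery cohort, by subtype.
CHRCC_MARGINALS = {
    "metastatic": 16 / 18,
    "prior_therapy": 11 / 18,
    "sarcomatoid_rhabdoid": 6 / 18,
    "imdc": {"favorable": 3 / 18, "intermediate": 7 / 18, "poor": 4 / 18,
             "not_applicable": 3 / 18, "missing": 1 / 18},
}
CCRCC_MARGINALS = {
    "metastatic": 197 / 197,
    "prior_therapy": 4 / 197,
    "sarcomatoid_rhabdoid": 41 / 197,
    "imdc": {"favorable": 37 / 197, "intermediate": 97 / 197, "poor": 25 / 197,
             "not_applicable": 0.0, "missing": 38 / 197},
}


def _default_planted_up():
    # 18 mitochondrial analytes spanning the observed effect range plus six
    # non-mitochondrial ones; indices 0..399 carry the mitochondrial flag by
    # default, so the first 18 fall inside the flagged block.
    mito_deltas = np.round(np.linspace(3.8, 2.5, 18), 2)
    extra = [(400, 3.1), (401, 2.9), (402, 2.7), (403, 3.3), (404, 2.6), (405, 3.0)]
    return tuple([(i, float(d)) for i, d in enumerate(mito_deltas)] + extra)


def _default_planted_down():
    return ((406, -2.5), (407, -1.2), (408, -1.0))


@dataclasses.dataclass
class SyntheticCohortSpec:
    """All knobs of the cohort generator.

    ``planted_up`` / ``planted_down`` are sequences of (analyte index,
    log2FC delta); indices must be disjoint.  ``baseline_mean_log2`` is the
    uniform range the per-analyte baseline means are drawn from.
    """

    n_case: int = 18
    n_control: int = 197
    n_analytes: int = 1000
    n_mito_flagged: int = 400
    planted_up: Sequence = dataclasses.field(default_factory=_default_planted_up)
    planted_down: Sequence = dataclasses.field(default_factory=_default_planted_down)
    baseline_mean_log2: tuple = (6.0, 12.0)
    within_group_sd: float = 1.0
    survival_beta: float = 0.8
    baseline_hazard: float = np.log(2) / 24.0  # median OS 24 months at score 0
    censor_fraction: float = 0.4
    seed: int = 0

    def validate(self):
        errors = []
        if self.n_case < 2 or self.n_control < 2:
            errors.append("group sizes must be >= 2")
        if self.n_analytes < 1:
            errors.append("n_analytes must be >= 1")
        if not 0 <= self.n_mito_flagged <= self.n_analytes:
            errors.append("n_mito_flagged must lie in [0, n_analytes]")
        if self.within_group_sd <= 0:
            errors.append("within_group_sd must be > 0")
        if not 0 <= self.censor_fraction < 1:
            errors.append("censor_fraction must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            errors.append("baseline_hazard must be > 0")
        lo, hi = self.baseline_mean_log2
        if not lo < hi:
            errors.append("baseline_mean_log2 range must satisfy lo < hi")
        idx_up = [i for i, _ in self.planted_up]
        idx_dn = [i for i, _ in self.planted_down]
        allidx = idx_up + idx_dn
        if len(set(allidx)) != len(allidx):
            errors.append("planted indices must be disjoint")
        if allidx and (min(allidx) < 0 or max(allidx) >= self.n_analytes):
            errors.append("planted indices out of range")
        if any(d <= 0 for _, d in self.planted_up):
            errors.append("planted_up deltas must be positive")
        if any(d >= 0 for _, d in self.planted_down):
            errors.append("planted_down deltas must be negative")
        if errors:
            raise ValueError("invalid SyntheticCohortSpec: " + "; ".join(errors))
        return self

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["planted_up"] = [[int(i), float(v)] for i, v in self.planted_up]
        d["planted_down"] = [[int(i), float(v)] for i, v in self.planted_down]
        d["baseline_mean_log2"] = list(self.baseline_mean_log2)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "planted_up" in d:
            d["planted_up"] = tuple((int(i), float(v)) for i, v in d["planted_up"])
        if "planted_down" in d:
            d["planted_down"] = tuple((int(i), float(v)) for i, v in d["planted_down"])
        if "baseline_mean_log2" in d:
            d["baseline_mean_log2"] = tuple(d["baseline_mean_log2"])
        return cls(**d)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth: per-analyte delta, per-sample score, survival params."""

    delta: pd.Series          # true log2FC (case minus control) per analyte
    true_score: pd.Series     # standardized per-sample signature score
    survival_beta: float
    baseline_hazard: float


def _rng_for(spec: SyntheticCohortSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def generate_cohort(spec: SyntheticCohortSpec):
    """Generate a raw-RFU cohort and its ground truth.

    log2 intensities are Normal(baseline_p + group * delta_p, sd); RFU is
    their exponential (2**log2), hence strictly positive.  Clinical
    covariates are drawn independently of expression with the study's
    marginal frequencies by subtype.  Reproducible by seed.

    Returns ``(ExpressionDataset [raw], SyntheticTruth)``.
    """
    spec.validate()
    rng = _rng_for(spec, 0)
    n = spec.n_case + spec.n_control
    p = spec.n_analytes

    delta = np.zeros(p)
    for i, d in spec.planted_up:
        delta[i] = d
    for i, d in spec.planted_down:
        delta[i] = d

    baseline = rng.uniform(*spec.baseline_mean_log2, size=p)
    group = np.concatenate([np.ones(spec.n_case), np.zeros(spec.n_control)])
    log2x = (baseline[None, :] + np.outer(group, delta)
             + rng.normal(0.0, spec.within_group_sd, size=(n, p)))

    seq_ids = pd.Index([f"seq-{i + 1:05d}" for i in range(p)], name="seq_id")
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    analytes = pd.DataFrame({
        "gene_symbol": [f"GENE{i + 1:04d}" for i in range(p)],
        "protein_name": [f"protein {i + 1}" for i in range(p)],
        "is_mitochondrial": np.arange(p) < spec.n_mito_flagged,
    }, index=seq_ids)

    samples = _draw_clinical(spec, rng, sample_ids, group)
    rfu = pd.DataFrame(np.exp2(log2x), index=sample_ids, columns=seq_ids)

    mito_up = [i for i, _ in spec.planted_up if i < spec.n_mito_flagged]
    basis = mito_up or [i for i, _ in spec.planted_up] or None
    if basis is not None:
        raw = log2x[:, basis].sum(axis=1)
        sd = raw.std(ddof=1)
        score = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    else:
        score = np.zeros(n)

    truth = SyntheticTruth(
        delta=pd.Series(delta, index=seq_ids, name="delta"),
        true_score=pd.Series(score, index=sample_ids, name="true_score"),
        survival_beta=spec.survival_beta,
        baseline_hazard=spec.baseline_hazard,
    )
    dataset = ExpressionDataset(
        rfu, analytes, samples, scale="raw",
        provenance=[{"op": "generate_cohort", "seed": int(spec.seed),
                     "n_case": spec.n_case, "n_control": spec.n_control}],
    )
    return dataset, truth


def _draw_clinical(spec, rng, sample_ids, group) -> pd.DataFrame:
    rows = []
    for g in group:
        m = CHRCC_MARGINALS if g == 1 else CCRCC_MARGINALS
        imdc_levels = list(m["imdc"].keys())
        imdc_probs = np.array(list(m["imdc"].values()))
        rows.append({
            "subtype": "ChRCC" if g == 1 else "ccRCC",
            "metastatic": bool(rng.random() < m["metastatic"]),
            "prior_therapy": bool(rng.random() < m["prior_therapy"]),
            "imdc": imdc_levels[rng.choice(len(imdc_levels),
                                           p=imdc_probs / imdc_probs.sum())],
            "sarcomatoid_rhabdoid": bool(rng.random() < m["sarcomatoid_rhabdoid"]),
            "os_time": np.nan,
            "os_event": np.nan,
        })
    return pd.DataFrame(rows, index=sample_ids)


def attach_survival(dataset: ExpressionDataset, truth: SyntheticTruth,
                    spec: SyntheticCohortSpec) -> ExpressionDataset:
    """Attach overall survival driven by the true signature score.

    Event times are exponential with hazard h0 * exp(beta * score); an
    independent Uniform(0, c) censoring time is applied, with c calibrated
    on the drawn times so the realized censored fraction lands within 0.05
    of ``spec.censor_fraction``.
    """
    rng = _rng_for(spec, 1)
    score = truth.true_score.loc[dataset.rfu.index].to_numpy()
    hazard = spec.baseline_hazard * np.exp(spec.survival_beta * score)
    t_event = rng.exponential(1.0 / hazard)
    t_event = np.maximum(t_event, 1e-6)

    samples = dataset.samples.copy()
    if spec.censor_fraction == 0:
        samples["os_time"] = t_event
        samples["os_event"] = 1.0
    else:
        u = rng.random(len(t_event))
        # realized censored fraction is monotone decreasing in c; bisect
        lo, hi = 1e-9, 100.0 * float(t_event.max())
        for _ in range(200):
            c = 0.5 * (lo + hi)
            frac = float((u * c < t_event).mean())
            if frac > spec.censor_fraction:
                lo = c
            else:
                hi = c
        c = 0.5 * (lo + hi)
        censored = u * c < t_event
        samples["os_time"] = np.where(censored, np.maximum(u * c, 1e-6), t_event)
        samples["os_event"] = np.where(censored, 0.0, 1.0)
    return ExpressionDataset(
        dataset.rfu, dataset.analytes, samples, scale=dataset.scale,
        provenance=dataset.provenance + [{
            "op": "attach_survival", "survival_beta": spec.survival_beta,
            "censor_fraction": spec.censor_fraction}],
    )


def generate_paired_tissue(n_pairs: int, shift: float, sd: float, seed: int = 0
                           ) -> pd.DataFrame:
    """Paired tumor / matched-normal abundances for the signed-rank test.

    tumor = normal + shift + Normal(0, sd); ``sd = 0`` makes all differences
    exactly ``shift``.
    """
    if n_pairs < 5:
        raise ValueError("need n_pairs >= 5")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    normal = rng.normal(8.0, 1.0, size=n_pairs)
    tumor = normal + shift + (rng.normal(0.0, sd, size=n_pairs) if sd > 0 else 0.0)
    return pd.DataFrame({"pair": np.arange(1, n_pairs + 1),
                         "normal": normal, "tumor": tumor}).set_index("pair")


def generate_bridging_fixture(dataset: ExpressionDataset,
                              scalar_range=(0.5, 2.0), seed: int = 0):
    """Perturb a raw dataset so that harmonization recovers it exactly.

    Each analyte's RFU is divided by a scalar drawn uniformly from
    ``scalar_range``; applying :func:`mitosig.dataset.harmonize` with the
    returned table inverts the perturbation (within 1e-9 relative).
    """
    if dataset.scale != "raw":
        raise DatasetError("bridging fixtures are generated on raw RFU")
    lo, hi = scalar_range
    if not (0 < lo <= hi):
        raise ValueError("scalar_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    scalars = pd.Series(rng.uniform(lo, hi, size=dataset.n_analytes),
                        index=dataset.rfu.columns)
    perturbed = ExpressionDataset(
        dataset.rfu / scalars, dataset.analytes.copy(), dataset.samples.copy(),
        scale="raw",
        provenance=dataset.provenance + [{"op": "generate_bridging_fixture"}],
        validate=False,
    )
    return perturbed, BridgingTable(scalars)


def generate_gene_sets(analytes: pd.DataFrame, truth: SyntheticTruth,
                       n_random_sets: int = 12, set_size=(10, 40),
                       seed: int = 0) -> GeneSetCollection:
    """Gene-set collection over the synthetic gene namespace.

    One set collects the genes of the planted upregulated analytes (the
    "planted pathway"); the rest are random draws from the panel, so ORA on
    the synthetic cohort has a known positive and calibrated negatives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    genes = analytes["gene_symbol"].astype(str).str.upper().to_numpy()
    up_genes = sorted(set(genes[(truth.delta.to_numpy() > 0)]))
    sets = {}
    if up_genes:
        sets["PLANTED_UP"] = ("planted upregulated analytes", tuple(up_genes))
    lo, hi = set_size
    for k in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(np.unique(genes), size=min(size, len(set(genes))),
                             replace=False)
        sets[f"RANDOM_{k + 1:02d}"] = (f"random set {k + 1}", tuple(members))
    return GeneSetCollection(name="synthetic", sets=sets)
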