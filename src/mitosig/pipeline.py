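"""End-to-end pipeline: ingest -> harmonize -> DE -> enrichment ->
mitochondria-restricted stability LASSO -> score -> survival.

A single :class:`PipelineConfig` (YAML/JSON) drives the run; the output
directory receives seven text artifacts:

* ``de_table.tsv``            -- per-analyte moderated-t results and calls
* ``enrichment.tsv``          -- gene-set over-representation table
* ``stability_model.json``    -- the serialized stability-selection results
* ``roc_overall.tsv``         -- ROC points of the final score, full cohort
* ``roc_subsets.tsv``         -- ROC points per clinical subset
* ``survival_results.json``   -- multivariable adjustment + score survival
* ``manifest.json``           -- versions, seed, config hash, dropped counts

The manifest contains no wall-clock information, so identical seeds yield
bit-identical manifests; timings and per-stage progress go to the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dataset as ds, diffexpr, enrichment, signature, survival
from . import synthetic as syn

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("mitosig")

ARTIFACTS = (
    "de_table.tsv", "enrichment.tsv", "stability_model.json", "roc_overall.tsv",
    "roc_subsets.tsv", "survival_results.json", "manifest.json",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    synthetic: syn.SyntheticCohortSpec | None = None
    input_paths: dict | None = None     # adat | matrix/samples/analytes, bridging, mito_genes
    gene_sets: str | None = None
    lfc: float = 1.0
    fdr: float = 0.05
    selection: float = 1 / 3
    pathway_fdr: float = 0.05
    iterations: int = 100
    seed: int = 0
    subsets: tuple = ("metastatic_only", "treatment_naive")
    maxstat_permutations: int = 0

    def to_dict(self):
        return {
            "outdir": str(self.outdir),
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "input_paths": self.input_paths,
            "gene_sets": self.gene_sets,
            "thresholds": {"lfc": self.lfc, "fdr": self.fdr,
                           "selection": self.selection,
                           "pathway_fdr": self.pathway_fdr},
            "iterations": self.iterations,
            "seed": self.seed,
            "subsets": list(self.subsets),
            "maxstat_permutations": self.maxstat_permutations,
        }


def validate_config(raw: dict) -> tuple:
    """Validate a raw config mapping; all violations are reported at once.

    Returns ``(PipelineConfig, warnings)``.
    """
    errors, warns = [], []
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    has_synth = raw.get("synthetic") is not None
    has_input = raw.get("input") is not None
    if has_synth == has_input:
        errors.append("exactly one of 'synthetic' and 'input' must be set")
    spec = None
    if has_synth and not has_input:
        try:
            spec = syn.SyntheticCohortSpec.from_dict(raw["synthetic"]).validate()
        except (TypeError, ValueError) as exc:
            errors.append(f"synthetic spec invalid: {exc}")
    input_paths = raw.get("input")
    if has_input and input_paths is not None:
        if not isinstance(input_paths, dict):
            errors.append("'input' must be a mapping of paths")
        elif not ("adat" in input_paths
                  or {"matrix", "samples", "analytes"} <= set(input_paths)):
            errors.append("'input' needs either 'adat' or all of "
                          "'matrix'/'samples'/'analytes'")

    th = raw.get("thresholds", {})
    defaults = {"lfc": 1.0, "fdr": 0.05, "selection": 1 / 3, "pathway_fdr": 0.05}
    values = {}
    for key, dflt in defaults.items():
        v = th.get(key, dflt)
        try:
            v = float(v)
        except (TypeError, ValueError):
            errors.append(f"threshold {key!r} must be numeric")
            continue
        if key == "lfc" and v < 0:
            errors.append("lfc threshold must be >= 0")
        if key in ("fdr", "pathway_fdr", "selection") and not 0 < v <= 1:
            errors.append(f"threshold {key!r} must lie in (0, 1]")
        values[key] = v

    iterations = raw.get("iterations", 100)
    if not isinstance(iterations, int) or iterations < 1:
        errors.append("iterations must be a positive integer")
    if "seed" not in raw:
        warns.append("no seed given; defaulting to 0")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
    if "outdir" not in raw:
        errors.append("outdir is required")
    perms = raw.get("maxstat_permutations", 0)
    if not isinstance(perms, int) or perms < 0:
        errors.append("maxstat_permutations must be a non-negative integer")

    if errors:
        raise ConfigError("; ".join(errors))
    config = PipelineConfig(
        outdir=raw["outdir"], synthetic=spec, input_paths=input_paths,
        gene_sets=raw.get("gene_sets"), iterations=iterations, seed=seed,
        subsets=tuple(raw.get("subsets", ("metastatic_only", "treatment_naive"))),
        maxstat_permutations=perms, **values,
    )
    return config, warns


def load_config(path) -> tuple:
    """Read a YAML/JSON config file and validate it."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def _ingest(config: PipelineConfig):
    """Stage 1: obtain the raw dataset (synthetic or from files)."""
    counts = {}
    truth = None
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        data, truth = syn.generate_cohort(spec)
        data = syn.attach_survival(data, truth, spec)
        counts["harmonize_dropped"] = 0
        return data, truth, counts
    paths = config.input_paths
    if "adat" in paths:
        data = ds.read_adat(paths["adat"])
    else:
        data = ds.read_tsv_dataset(paths["matrix"], paths["samples"], paths["analytes"])
    if paths.get("bridging"):
        table = ds.read_bridging_table(paths["bridging"])
        data = ds.harmonize(data, table)
        counts["harmonize_dropped"] = data.provenance[-1]["n_dropped"]
    else:
        counts["harmonize_dropped"] = 0
    if paths.get("mito_genes"):
        data = ds.flag_mitochondrial(data, ds.read_gene_list(paths["mito_genes"]))
    return data, truth, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns a result dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    stages = {}
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %s: start", name)
        stages[name] = time.perf_counter()

    def done(name):
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - stages[name])

    try:
        stage("ingest")
        data, truth, counts = _ingest(config)
        counts["n_samples"] = data.n_samples
        counts["n_analytes"] = data.n_analytes
        done("ingest")

        stage("de")
        log2 = data.log2()
        de_res = diffexpr.ModeratedTTest(
            log2, lfc_threshold=config.lfc, fdr_threshold=config.fdr).fit()
        de_res.to_tsv(outdir / "de_table.tsv")
        counts["n_de_up"] = de_res.n_up
        counts["n_de_down"] = de_res.n_down
        done("de")

        stage("enrichment")
        if config.gene_sets:
            collection = enrichment.read_gmt(config.gene_sets)
        elif truth is not None:
            collection = syn.generate_gene_sets(data.analytes, truth,
                                                seed=config.seed)
        else:
            collection = enrichment.read_gmt(_packaged_gmt(), name="mito_mini")
        enr_table, skipped = enrichment.ora_test(
            de_res.upregulated_genes(), de_res.universe_genes(), collection)
        enr_out = enr_table.copy()
        enr_out.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.6g")
        counts["n_enrichment_skipped_sets"] = len(skipped)
        counts["n_enrichment_significant"] = (
            int((enr_table["q"] <= config.pathway_fdr).sum()) if len(enr_table) else 0)
        done("enrichment")

        stage("stability")
        model = signature.StabilitySelection.from_dataset(log2, restrict_mito=True)
        results = model.fit(n_iterations=config.iterations,
                            threshold=config.selection, seed=config.seed)
        results.save_json(outdir / "stability_model.json")
        counts["n_retained_features"] = len(results.retained_features)
        done("stability")

        stage("score")
        subset_masks = _subset_masks(log2, config.subsets)
        if not results.no_stable_features:
            overall = results.roc()
            overall.to_frame().to_csv(outdir / "roc_overall.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            table, curves, skipped_subsets = signature.subset_sensitivity(
                log2, results, subsets=subset_masks)
            rows = []
            for name, curve in curves.items():
                frame = curve.to_frame()
                frame.insert(0, "subset", name)
                frame["auroc"] = curve.auc
                rows.append(frame)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    outdir / "roc_subsets.tsv", sep="\t", index=False,
                    float_format="%.6g")
            else:
                (outdir / "roc_subsets.tsv").write_text(
                    "# every subset lacked a class\n")
            counts["subset_auroc"] = {k: float(v) for k, v in table["auroc"].items()}
            counts["subsets_skipped"] = skipped_subsets
        else:
            for f in ("roc_overall.tsv", "roc_subsets.tsv"):
                (outdir / f).write_text("# no stable features retained\n")
        done("score")

        stage("survival")
        surv = _survival_stage(log2, results, config)
        with open(outdir / "survival_results.json", "w") as fh:
            json.dump(surv, fh, indent=1, sort_keys=True)
            fh.write("\n")
        done("survival")

        manifest = {
            "mitosig_version": __version__,
            "library_versions": _library_versions(),
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "counts": counts,
            "artifacts": list(ARTIFACTS),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
        return {"outdir": str(outdir), "counts": counts, "manifest": manifest,
                "de": de_res, "stability": results}
    except Exception:
        logger.exception("pipeline failed (partial outputs retained in %s)", outdir)
        raise


def _subset_masks(log2, subset_names):
    masks = {}
    s = log2.samples
    if "metastatic_only" in subset_names:
        masks["metastatic_only"] = s["metastatic"].astype(bool).to_numpy()
    if "treatment_naive" in subset_names:
        masks["treatment_naive"] = ~s["prior_therapy"].astype(bool).to_numpy()
    return masks


def _survival_stage(log2, results, config) -> dict:
    out = {"multivariable": None, "score_survival": None, "notes": []}
    if results.no_stable_features:
        out["notes"].append("no stable features: survival stage skipped")
        return out
    scores = results.score(log2.rfu)
    y = (log2.samples["subtype"] == "ChRCC").astype(int).to_numpy()
    covs = log2.samples[["prior_therapy", "imdc", "sarcomatoid_rhabdoid"]]
    try:
        mv = signature.multivariable_logistic(scores.to_numpy(), covs, y)
        out["multivariable"] = json.loads(mv.reset_index().to_json(orient="records"))
    except ValueError as exc:
        out["notes"].append(f"multivariable adjustment skipped: {exc}")

    cases = log2.samples[log2.samples["subtype"] == "ChRCC"]
    with_surv, n_dropped = survival.drop_missing_survival(cases)
    out["n_missing_survival_dropped"] = n_dropped
    if len(with_surv) >= 10:
        sc = scores.loc[with_surv.index].to_numpy()
        t = with_surv["os_time"].to_numpy()
        e = with_surv["os_event"].to_numpy()
        try:
            ms = survival.maxstat_cutpoint(
                sc, t, e, n_permutations=config.maxstat_permutations,
                seed=config.seed)
            groups = ms.groups(sc)
            lr = survival.logrank_test(t, e, groups == "high")
            cox = survival.cox_univariable(t, e, sc)
            out["score_survival"] = {
                "n": int(len(with_surv)),
                "n_events": int(e.sum()),
                "cutpoint": ms.cutpoint,
                "max_chi_sq": ms.max_chi_sq,
                "logrank_p_naive": ms.p_naive,
                "logrank_p_permutation": ms.p_permutation,
                "logrank_chi_sq": lr.chi_sq,
                "cox_hr_per_score_unit": cox.hr,
                "cox_ci95": list(cox.ci95),
                "cox_p": cox.p,
            }
        except ValueError as exc:
            out["notes"].append(f"score survival skipped: {exc}")
    else:
        out["notes"].append("fewer than 10 cases with survival; stage skipped")
    return out


def _packaged_gmt():
    from importlib import resources

    return resources.files("mitosig").joinpath("data/mito_pathways_mini.gmt")


def _library_versions():
    import importlib.metadata as md

    out = {}
    for name in ("numpy", "scipy", "pandas", "scikit-learn", "statsmodels",
                 "lifelines", "numba"):
        try:
            out[name] = md.version(name)
        except md.PackageNotFoundError:
            out[name] = None
    return out


def _config_hash(config: PipelineConfig) -> str:
    # the output directory is a run location, not an analysis parameter
    payload = config.to_dict()
    payload.pop("outdir")
    canon = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def _setup_logging(outdir: Path):
    if not logger.handlers:
        logger.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(sh)
    # one file handler per outdir
    logpath = outdir / "pipeline.log"
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logpath)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
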