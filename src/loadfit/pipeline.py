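"""Pipeline orchestration: simulate -> load -> fit -> screen -> report.

A single :class:`RunConfig` (YAML-loadable) drives all stages. Every stage
logs one line with input/output record counts; any failure aborts with the
stage name and cause. The machine-readable ``report.json`` holds versions, a
config hash, per-stage counts, every fitted model, screen hits and a
group-level summary of litter size, longevity and LRS per ancestry class.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import load_metrics as lm
from . import fitness_models as fm
from . import candidate_screen as cs
from . import synthetic_data as sd

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("loadfit")

LM_PREDICTORS = ("e_lof", "m_lof", "e_mis", "e_syn", "het_per_kb")
LM_RESPONSES = ("lrs_sqrt", "longevity_log", "litter_size")
GLM_PREDICTORS = ("e_lof", "e_mis", "e_syn", "het_per_kb")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 42
    # either simulate ...
    simulate: dict | None = None
    # ... or point at existing inputs
    vcf: str | None = None
    metadata: str | None = None
    litters: str | None = None
    terms: str | None = None
    callable_length_bp: float | None = None
    load_denominator: str = "all_sites"
    screen_freq_threshold: float = 0.20
    screen_min_hom_fraction: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as err:
            raise ValueError(f"invalid config: {err}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("vcf", "metadata"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"config must set either 'simulate' or {name!r}")
                if not Path(value).exists():
                    raise ValueError(f"{name} file not found: {value}")
            for name in ("litters", "terms"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    raise ValueError(f"{name} file not found: {value}")
            if self.callable_length_bp is None or self.callable_length_bp <= 0:
                raise ValueError("callable_length_bp must be positive when "
                                 "analysing an existing VCF")
        if self.load_denominator not in ("all_sites", "carrier_sites"):
            raise ValueError("load_denominator must be all_sites or carrier_sites")
        if not 0 <= self.screen_freq_threshold <= 1:
            raise ValueError("screen_freq_threshold must be in [0, 1]")
        if not 0 <= self.screen_min_hom_fraction <= 1:
            raise ValueError("screen_min_hom_fraction must be in [0, 1]")

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location and logging
        verbosity excluded, so reruns into different directories match)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, err) from err
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(cfg: RunConfig, out: Path) -> dict:
    params = dict(cfg.simulate or {})
    params.setdefault("seed", cfg.seed)
    sim_cfg = sd.SimConfig(**params)
    result = sd.simulate_population(sim_cfg)
    paths = sd.write_outputs(result, out / "sim")
    log.info("simulate: %d pedigree rows, %d litters, %d sites -> %s",
             len(result.pedigree), len(result.litters), len(result.positions),
             out / "sim")
    return {
        "vcf": str(paths["vcf"]),
        "metadata": str(paths["fitness"]),
        "litters": str(paths["litters"]),
        "callable_length_bp": float(sim_cfg.genome_length),
        "counts": {
            "individuals": int(len(result.pedigree)),
            "litters": int(len(result.litters)),
            "sites": int(len(result.positions)),
            "panel": len(result.panel_ids),
        },
    }


@_stage("load")
def _run_load(cfg: RunConfig, out: Path, vcf: str,
              callable_length_bp: float) -> dict:
    table = lm.read_annotated_vcf(vcf)
    filtered, removed = lm.apply_site_filters(table)
    profiles = lm.compute_load_profiles(filtered, callable_length_bp,
                                        denominator=cfg.load_denominator)
    lm.write_load_profiles(profiles, out / "load_profiles.tsv")
    sfs = {}
    for cat in (lm.ImpactCategory.LOF, lm.ImpactCategory.MISSENSE,
                lm.ImpactCategory.SYNONYMOUS):
        s = lm.compute_sfs(filtered, cat)
        lm.write_sfs(s, out / f"sfs_{cat.value.lower()}.tsv")
        sfs[cat.value] = s
    log.info("load: %d sites in, removed %s, %d retained, %d samples",
             table.n_sites, removed, filtered.n_sites, filtered.n_samples)
    return {"table": filtered, "profiles": profiles, "removed": removed,
            "sfs": sfs, "n_sites_in": table.n_sites}


@_stage("fit")
def _run_fit(cfg: RunConfig, out: Path, profiles: pd.DataFrame,
             metadata_path: str, litters_path: str | None) -> dict:
    meta = pd.read_csv(metadata_path, sep="\t", na_values=["NA"])
    data = profiles.merge(meta, on="id", how="inner")
    models: dict[str, dict] = {}

    def try_fit(name, fn, *args, **kwargs):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models[name] = fn(*args, **kwargs).to_dict()
        except (ValueError, fm.SeparationError) as err:
            log.warning("fit: %s skipped (%s)", name, err)
            models[name] = {"skipped": str(err)}

    for response in LM_RESPONSES:
        for pred in LM_PREDICTORS:
            try_fit(f"lm_{response}_{pred}", fm.fit_trait_lm, data, response, pred)
    for pred in GLM_PREDICTORS:
        try_fit(f"glm_juvenile_survival_{pred}",
                fm.fit_juvenile_survival_glm, data, pred)

    # allele-load ancestry comparison (native vs immigrant descendants)
    tests: dict[str, dict] = {}
    if "ancestry_class" in data.columns:
        native = data[data.ancestry_class == "native"]
        hybrid = data[data.ancestry_class.isin(["F1", "F2", "F3", "F4"])]
        if len(native) and len(hybrid):
            for prop in ("p_lof", "p_mis", "p_syn"):
                a = native[prop].dropna()
                b = hybrid[prop].dropna()
                if len(a) and len(b):
                    r = fm.mann_whitney_groups(a, b)
                    tests[f"mw_{prop}_native_vs_hybrid"] = {
                        "u": r.u, "p": r.pvalue, "shift": r.shift,
                        "ci": list(r.ci), "method": r.method,
                        "n": [int(len(a)), int(len(b))],
                    }
    for pred in ("e_syn", "e_mis", "e_lof"):
        sub = data[["het_per_kb", pred]].dropna()
        if len(sub) >= 3 and sub[pred].nunique() > 1:
            c = fm.correlate(sub["het_per_kb"], sub[pred])
            tests[f"correlation_het_{pred}"] = {
                "r": c.r, "t": c.t, "p": c.pvalue, "ci": list(c.ci), "n": c.n}

    # ancestry mixed models on the full metadata (not only the panel)
    meta_all = meta.copy()
    meta_all["ancestry_group"] = fm.pool_ancestry(meta_all["ancestry_class"])
    lmm_data = meta_all.dropna(subset=["ancestry_group"])
    for response in ("lrs_sqrt", "longevity_log"):
        try:
            m = fm.fit_ancestry_lmm(lmm_data, response, "ancestry_group",
                                    fixed=("rodent_phase", "sex"),
                                    reference="native")
            models[f"lmm_{response}_ancestry"] = m.to_dict()
        except (ValueError, KeyError) as err:
            log.warning("fit: lmm %s skipped (%s)", response, err)
    if litters_path is not None:
        litters = pd.read_csv(litters_path, sep="\t", na_values=["NA"])
        litters["rodent_phase"] = [
            "increase" if ph == "increase" else "decrease"
            for ph in litters.get("rodent_phase",
                                  pd.Series(["increase"] * len(litters)))]
        try:
            m = fm.fit_ancestry_lmm(litters, "litter_size", "pair_combination",
                                    fixed=("rodent_phase",), random="den",
                                    reference="native_x_native")
            models["lmm_litter_size_pair"] = m.to_dict()
        except (ValueError, KeyError) as err:
            log.warning("fit: litter lmm skipped (%s)", err)

    # Table-1-style group summary from the metadata
    summary = {}
    adults = meta_all[meta_all["juvenile_survival"] == 1]
    for group, sub in adults.groupby("ancestry_group", observed=True):
        summary[str(group)] = {
            "n": int(len(sub)),
            "mean_longevity": (round(float(sub.longevity_years.mean()), 2)
                               if sub.longevity_years.notna().any() else None),
            "mean_lrs": (round(float(sub.lrs.mean()), 2)
                         if sub.lrs.notna().any() else None),
            "mean_litter_size": (round(float(sub.mean_litter_size.mean()), 2)
                                 if sub.mean_litter_size.notna().any() else None),
        }
    log.info("fit: %d models, %d tests, %d summary groups",
             len(models), len(tests), len(summary))
    return {"models": models, "tests": tests, "group_summary": summary,
            "caveat": "p-values not adjusted for multiple testing"}


@_stage("screen")
def _run_screen(cfg: RunConfig, out: Path, table: lm.VariantTable,
                metadata_path: str, terms_path: str | None) -> dict:
    meta = pd.read_csv(metadata_path, sep="\t", na_values=["NA"]).set_index("id")
    panel = [s for s in table.samples if s in meta.index]
    meta = meta.loc[panel]
    result: dict = {}

    native = [s for s in panel if meta.loc[s, "ancestry_class"] == "native"]
    hybrid = [s for s in panel
              if meta.loc[s, "ancestry_class"] in ("F1", "F2", "F3", "F4")]
    hits_all = []
    if native and hybrid:
        priv = cs.hybrid_private_lofs(table, native, hybrid,
                                      cfg.screen_freq_threshold)
        priv.to_csv(out / "screen_hybrid_private.tsv", sep="\t", index=False)
        result["hybrid_private"] = int(len(priv))
        hits_all.append(priv)

    litter = meta["mean_litter_size"].dropna()
    if len(litter) >= 8:
        low = list(litter.nsmallest(4).index)
        high = list(litter.nlargest(4).index)
        hits = cs.litter_size_screen(table, low, high)
        hits.to_csv(out / "screen_litter_size.tsv", sep="\t", index=False)
        result["litter_size"] = int(len(hits))
        hits_all.append(hits)

    longevity = meta["longevity_years"].dropna()
    if len(longevity) >= 8:
        short = list(longevity.nsmallest(max(4, int(0.5 * len(longevity)))).index)
        long_ = list(longevity.nlargest(4).index)
        short = [s for s in short if s not in long_]
        hits = cs.longevity_screen(table, short, long_,
                                   cfg.screen_min_hom_fraction)
        hits.to_csv(out / "screen_longevity.tsv", sep="\t", index=False)
        result["longevity"] = int(len(hits))
        hits_all.append(hits)

    if terms_path is not None and hits_all:
        term_df = pd.read_csv(terms_path, sep="\t")
        universe = sorted(set(table.sites.loc[
            table.class_mask(lm.ImpactCategory.LOF), "gene"]) - {""})
        candidates = sorted(
            set(pd.concat(hits_all)["gene"]) & set(universe))
        if candidates:
            enrich = cs.overrepresentation_test(candidates, universe, term_df)
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            result["enrichment_terms_tested"] = int(len(enrich))
            result["enrichment_min_p_bonferroni"] = (
                float(enrich["p_bonferroni"].min()) if len(enrich) else None)
    log.info("screen: %s", result)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write ``report.json``.

    Returns the report dict. Raises :class:`PipelineError` naming the failed
    stage on any error; validation problems surface before any compute.
    """
    config.validate()
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "loadfit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    if config.simulate is not None:
        sim = _run_simulate(config, out)
        vcf, metadata = sim["vcf"], sim["metadata"]
        litters = sim["litters"]
        callable_length = sim["callable_length_bp"]
        report["stages"]["simulate"] = sim["counts"]
    else:
        vcf, metadata = config.vcf, config.metadata
        litters = config.litters
        callable_length = float(config.callable_length_bp)

    loaded = _run_load(config, out, vcf, callable_length)
    report["stages"]["load"] = {
        "n_sites_in": loaded["n_sites_in"],
        "n_sites_retained": loaded["table"].n_sites,
        "removed": loaded["removed"],
        "n_samples": loaded["table"].n_samples,
        "mean_derived_frequency": {
            cat: (None if np.isnan(s.mean_derived_frequency)
                  else round(s.mean_derived_frequency, 4))
            for cat, s in loaded["sfs"].items()},
    }

    fitted = _run_fit(config, out, loaded["profiles"], metadata, litters)
    report["stages"]["fit"] = fitted

    screened = _run_screen(config, out, loaded["table"], metadata, config.terms)
    report["stages"]["screen"] = screened

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    log.info("report written to %s", out / "report.json")
    return report
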