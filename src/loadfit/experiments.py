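"""Reusable validation experiments for the simulator + analysis stack.

Each experiment regenerates its data from scratch through the public package
surface (simulator -> VCF-equivalent variant table -> load metrics -> model
fits), so the numbers it reports are end-to-end measurements, not cached
values. All randomness derives from one master seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import fitness_models as fm
from .load_metrics import (ImpactCategory, apply_site_filters,
                           compute_load_profiles, compute_sfs)
from .synthetic_data import default_config, recovery_config, simulate_population

__all__ = [
    "recovery_experiment",
    "mann_whitney_type1_error",
    "survival_glm_type1_error",
    "direction_properties",
    "planted_longevity_table",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2 ** 31 - 1, size=n)


def recovery_experiment(n_replicates: int = 100, n: int = 500,
                        seed: int = 0) -> dict:
    """Coefficient recovery for the two headline causal effects.

    For each replicate: simulate the recovery scenario, recompute load
    profiles from the final birth cohort through the load-metrics path, then
    (a) fit the juvenile-survival binomial GLM (het/kb + expressed missense)
    on ``n`` juveniles and (b) the log-longevity OLS (expressed LoF) on ``n``
    adults. Reports the fraction of replicates with the correct coefficient
    sign and with the generating coefficient inside the 95% CI.
    """
    sign_h = cover_h = sign_l = cover_l = 0
    n_ok = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        cfg = recovery_config(seed=int(rep_seed))
        try:
            res = simulate_population(cfg)
        except Exception:
            continue  # extinct replicate: no data to fit
        n_ok += 1
        table, _ = apply_site_filters(res.variant_table("juveniles"))
        prof = compute_load_profiles(table, cfg.genome_length).set_index("id")
        fit = res.fitness.set_index("id").loc[prof.index]
        surv = pd.Series(res.juvenile_survival, index=res.juvenile_ids)
        rng = np.random.default_rng(int(rep_seed) + 7)

        juv = prof.copy()
        juv["juvenile_survival"] = surv.loc[juv.index].values
        juv = juv.iloc[np.sort(rng.choice(len(juv), min(n, len(juv)),
                                          replace=False))]
        g = fm.fit_juvenile_survival_glm(juv, ("het_per_kb", "e_mis"),
                                         covariates=())
        th = g.term("het_per_kb")
        sign_h += th["estimate"] > 0
        cover_h += th["ci"][0] <= cfg.beta_het_survival <= th["ci"][1]

        adults = prof.join(fit[["juvenile_survival", "longevity_years"]])
        adults = adults[adults["juvenile_survival"] == 1]
        adults = adults.iloc[np.sort(rng.choice(len(adults),
                                                min(n, len(adults)),
                                                replace=False))]
        m = fm.fit_trait_lm(adults, "longevity_log", "e_lof", covariates=())
        tl = m.term("e_lof")
        sign_l += tl["estimate"] < 0
        cover_l += tl["ci"][0] <= cfg.beta_lof_longevity <= tl["ci"][1]
    return {
        "n_replicates": n_ok,
        "sign_recovery_survival": sign_h / n_ok,
        "ci_coverage_survival": cover_h / n_ok,
        "sign_recovery_longevity": sign_l / n_ok,
        "ci_coverage_longevity": cover_l / n_ok,
        "true_beta_het_survival": recovery_config().beta_het_survival,
        "true_beta_lof_longevity": recovery_config().beta_lof_longevity,
    }


def mann_whitney_type1_error(n_replicates: int = 1000, n_per_group: int = 15,
                             seed: int = 0, alpha: float = 0.05) -> dict:
    """Null rejection rate of the Mann-Whitney test (both groups from one
    normal distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        rejections += fm.mann_whitney_groups(a, b).pvalue < alpha
    return {"rate": rejections / n_replicates, "n_replicates": n_replicates,
            "n_per_group": n_per_group}


def survival_glm_type1_error(n_replicates: int = 1000, n: int = 400,
                             seed: int = 0, alpha: float = 0.05) -> dict:
    """Null rejection rate of the binomial survival GLM: the predictor is
    independent of the outcome, covariates included as in the analysis."""
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < n_replicates:
        df = pd.DataFrame({
            "juvenile_survival": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
            "sex": rng.choice(["M", "F"], n),
            "rodent_phase": rng.choice(["increase", "decrease"], n),
        })
        try:
            res = fm.fit_juvenile_survival_glm(df, "x")
        except (ValueError, fm.SeparationError):
            continue
        rejections += res.term("x")["p"] < alpha
        done += 1
    return {"rate": rejections / n_replicates, "n_replicates": n_replicates,
            "n": n}


def direction_properties(seed: int = 0, n_replicates: int = 3) -> dict:
    """Qualitative directions on the default scenario, pooled over replicates.

    Reports per-class mean derived frequencies (SFS shift), the correlation
    between heterozygosity and expressed synonymous load on the written
    panel, and mean litter size per pair-ancestry combination.
    """
    mf = {"LOF": [], "SYNONYMOUS": [], "MISSENSE": []}
    het, e_syn = [], []
    litters = []
    n_ok = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        try:
            res = simulate_population(default_config(seed=int(rep_seed)))
        except Exception:
            continue
        n_ok += 1
        table, _ = apply_site_filters(res.variant_table("panel"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = compute_load_profiles(table, res.config.genome_length)
        for cat in (ImpactCategory.LOF, ImpactCategory.SYNONYMOUS,
                    ImpactCategory.MISSENSE):
            mf[cat.value].append(compute_sfs(table, cat).mean_derived_frequency)
        het.extend(prof["het_per_kb"])
        e_syn.extend(prof["e_syn"])
        litters.append(res.litters)
    litter_means = (pd.concat(litters).groupby("pair_combination")
                    ["litter_size"].mean().to_dict())
    corr = fm.correlate(het, e_syn)
    return {
        "n_replicates": n_ok,
        "mean_freq_lof": float(np.mean(mf["LOF"])),
        "mean_freq_synonymous": float(np.mean(mf["SYNONYMOUS"])),
        "mean_freq_missense": float(np.mean(mf["MISSENSE"])),
        "r_het_e_syn": corr.r,
        "r_het_e_syn_p": corr.pvalue,
        "litter_means": litter_means,
        "n_panel_individuals": len(het),
    }


def planted_longevity_table(seed: int = 0):
    """Constructed fixture for the longevity screen: 10 short-lived and 4
    long-lived individuals with (a) one planted variant homozygous in all
    short-lived and absent/het in all long-lived, (b) three planted variants
    homozygous in exactly 40-60% of the short-lived, and (c) background
    variants that violate the rules.

    Returns (table, short_ids, long_ids, strict_positions, relaxed_positions).
    """
    from .load_metrics import VariantTable

    rng = np.random.default_rng(seed)
    short = [f"short{i}" for i in range(10)]
    long_ = [f"long{i}" for i in range(4)]
    samples = short + long_

    rows, geno = [], []

    def add(pos, short_geno, long_geno):
        rows.append(("chr1", pos, "A", "T", "LOF", f"gene{pos}"))
        geno.append(list(short_geno) + list(long_geno))

    strict_pos = 1000
    add(strict_pos, [2] * 10, [1, 1, 0, 0])           # the all-homozygous hit
    relaxed_pos = [2000, 3000, 4000]
    add(2000, [2, 2, 2, 2, 1, 1, 1, 0, 0, 0], [0, 1, 0, 0])   # 40% hom
    add(3000, [2, 2, 2, 2, 2, 1, 0, 0, 0, 0], [1, 0, 0, 0])   # 50% hom
    add(4000, [2, 2, 2, 2, 2, 2, 0, 1, 1, 0], [0, 0, 1, 0])   # 60% hom
    # background: hom in a long-lived individual (vetoed)
    add(5000, [2] * 10, [2, 0, 0, 0])
    # background: too few short homozygotes
    add(6000, [2, 2, 1, 1, 1, 0, 0, 0, 0, 0], [0, 0, 0, 0])
    # background: random segregating noise, never >= 40% short hom
    for k in range(10):
        g_short = rng.choice([0, 1], size=10).tolist()
        g_long = rng.choice([0, 1], size=4).tolist()
        add(7000 + k, g_short, g_long)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "impact", "gene"])
    table = VariantTable(sites=sites,
                         genotypes=np.array(geno, dtype=np.int8),
                         samples=samples)
    return table, short, long_, {strict_pos}, {strict_pos, *relaxed_pos}
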