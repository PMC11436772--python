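"""Forward-in-time diploid simulator for a small, admixed population.

The simulator emulates the data structure of a closely monitored, inbred
arctic-fox-like population subject to genetic rescue: a handful of founders,
den-structured monogamous breeding, a 3-4 year rodent cycle driving
fecundity, an immigration event that introduces novel strongly deleterious
(HIGH-impact) alleles, and fitness traits causally driven by expressed
mutational load and genome-wide heterozygosity.

Genetics: diploid individuals on a single pseudo-autosomal chromosome;
infinite-sites mutation on a lattice of ``genome_length`` base pairs; one
crossover per meiosis at a uniform position; new mutations assigned a
functional class (LoF / missense / synonymous for coding, plus a neutral
non-coding class) by fixed probabilities. Purifying viability selection acts
per generation with fitness w = prod (1 - s*h)^het * (1 - s)^hom, strongest
and most recessive for the LoF class.

Traits are drawn per birth cohort from predictors computed over the sites
segregating within that cohort -- exactly the quantities the load-metrics
module recomputes from a VCF of the same cohort:

* juvenile survival ~ Bernoulli(w * logit^-1(a0 + b_het*het_kb + b_mis*e_mis))
* longevity (survivors) = (1 + Geometric) * exp(b_lof_longevity * e_lof), years
* per-year litter size ~ Poisson with rodent-phase and load effects plus a
  heterosis term; LRS = total cubs over the individual's breeding years.

All randomness flows from a single ``numpy`` Generator seeded by
``SimConfig.seed``; a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .load_metrics import VariantTable

__all__ = [
    "SimConfig",
    "SimulationResult",
    "ConfigError",
    "ExtinctionError",
    "simulate_population",
    "write_outputs",
    "default_config",
    "neutral_config",
    "recovery_config",
]

# site class codes (internal); NONCODING maps to MODIFIER impact downstream
LOF, MIS, SYN, NONCODING = 0, 1, 2, 3
CLASS_NAMES = ("lof", "missense", "synonymous", "noncoding")
ANN_TERMS = {
    LOF: ("stop_gained", "HIGH"),
    MIS: ("missense_variant", "MODERATE"),
    SYN: ("synonymous_variant", "LOW"),
    NONCODING: ("intergenic_region", "MODIFIER"),
}

# default apportioning of new coding mutations among classes, proportional to
# the segregating counts observed in the study system (LoF : mis : syn)
DEFAULT_CLASS_WEIGHTS = (1300.0, 44433.0, 86508.0)

_BASES = "ACGT"


class ConfigError(ValueError):
    """Raised when a SimConfig fails validation."""


class ExtinctionError(RuntimeError):
    """Population went extinct before the final generation."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(f"population extinct at generation {generation}")


@dataclass
class SimConfig:
    """All simulator parameters; see module docstring for the model.

    Mutation rates are per-genome per-generation means. Selection (s) and
    dominance (h) are per impact class: LoF large-s near-recessive, missense
    weak and partially dominant, synonymous neutral. Trait coefficients are
    on the scales of the analysis predictors (expressed-load proportions and
    heterozygous sites per kb).
    """

    n_founders: int = 36
    n_generations: int = 18
    carrying_capacity: int = 120
    genome_length: int = 2_000_000

    # mutation
    mu_coding: float = 1.5
    mu_noncoding: float = 6.0
    coding_class_weights: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS
    # founder standing variation: segregating sites per class (lof, mis, syn, nc)
    standing_sites: tuple[int, int, int, int] = (40, 400, 800, 1600)

    # selection / dominance per coding class
    s_lof: float = 0.35
    h_lof: float = 0.0
    s_mis: float = 0.02
    h_mis: float = 0.2
    s_syn: float = 0.0
    h_syn: float = 0.5

    # immigration
    immigration_generation: int = 15
    n_immigrants: int = 3
    immigrant_source_diversity: float = 1.0
    # weight of the independent source-population allele spectrum when drawing
    # immigrant genotypes at sites already segregating in the recipients
    immigrant_divergence: float = 0.6
    # novel source-private sites per class at diversity 1.0
    novel_site_base: tuple[int, int, int, int] = (15, 60, 120, 240)

    # trait coefficients (signs enforced at validation)
    beta_lof_lrs: float = -60.0
    beta_lof_longevity: float = -60.0
    beta_het_survival: float = 8.0
    beta_missense_survival: float = -30.0
    survival_intercept: float = 1.3
    adult_stop_prob: float = 0.45        # geometric lifespan parameter
    base_litter: float = 6.6             # mean cubs per litter (increase phase)
    litter_phase_decrease: float = 0.25  # log-scale litter bump in decrease years
    breed_prob_increase: float = 0.45
    breed_prob_decrease: float = 0.25
    heterosis_litter: float = 2.0        # per expected-offspring-het/kb
    het_reference: float = 0.30          # centring constant, het/kb scale
    lof_reference: float = 0.003         # centring constant, e_lof scale

    # environment / structure
    rodent_cycle_period: int = 4
    n_dens: int = 30
    den_sd: float = 0.15

    # output panel: subsample of the final birth cohort written to the VCF
    panel_size: int | None = 37

    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        if self.n_generations < 0 or self.carrying_capacity < 2:
            raise ConfigError("n_generations >= 0 and carrying_capacity >= 2 required")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be > 0")
        for name in ("mu_coding", "mu_noncoding", "immigrant_source_diversity"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("s_lof", "s_mis", "s_syn", "h_lof", "h_mis", "h_syn"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if any(w < 0 for w in self.coding_class_weights) or sum(self.coding_class_weights) <= 0:
            raise ConfigError("coding_class_weights must be non-negative with positive sum")
        if self.beta_lof_lrs > 0 or self.beta_lof_longevity > 0:
            raise ConfigError("beta_lof_lrs and beta_lof_longevity must be <= 0")
        if self.beta_het_survival < 0:
            raise ConfigError("beta_het_survival must be >= 0")
        if self.beta_missense_survival > 0:
            raise ConfigError("beta_missense_survival must be <= 0")
        if not 0.0 < self.adult_stop_prob < 1.0:
            raise ConfigError("adult_stop_prob must be in (0, 1)")
        if not 0.0 <= self.breed_prob_increase <= 1.0 or not 0.0 <= self.breed_prob_decrease <= 1.0:
            raise ConfigError("breeding probabilities must be in [0, 1]")
        if self.rodent_cycle_period < 2:
            raise ConfigError("rodent_cycle_period must be >= 2")
        if self.n_dens < 1 or self.den_sd < 0:
            raise ConfigError("n_dens >= 1 and den_sd >= 0 required")
        if self.panel_size is not None and self.panel_size < 1:
            raise ConfigError("panel_size must be None or >= 1")
        if self.n_immigrants < 0 or self.immigration_generation < 0:
            raise ConfigError("immigration settings must be non-negative")
        if not 0.0 <= self.immigrant_divergence <= 1.0:
            raise ConfigError("immigrant_divergence must be in [0, 1]")

    def rodent_phase(self, year: int) -> str:
        """Deterministic rodent phase: first half of each cycle is 'increase'."""
        half = self.rodent_cycle_period / 2
        return "increase" if (year % self.rodent_cycle_period) < half else "decrease"

    def selection_params(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([self.s_lof, self.s_mis, self.s_syn, 0.0])
        h = np.array([self.h_lof, self.h_mis, self.h_syn, 0.5])
        return s, h


def default_config(seed: int = 42, **overrides) -> SimConfig:
    """The default study-like scenario (selection, admixture, trait effects on)."""
    return SimConfig(seed=seed, **overrides)


def neutral_config(seed: int = 42, **overrides) -> SimConfig:
    """All selection coefficients and trait effects zero: pure drift."""
    params = dict(
        s_lof=0.0, s_mis=0.0, s_syn=0.0,
        beta_lof_lrs=0.0, beta_lof_longevity=0.0,
        beta_het_survival=0.0, beta_missense_survival=0.0,
        heterosis_litter=0.0,
        n_immigrants=0,
    )
    params.update(overrides)
    return SimConfig(seed=seed, **params)


def recovery_config(seed: int = 42, **overrides) -> SimConfig:
    """Scenario for coefficient-recovery experiments: selection off so load
    drifts freely, a large final cohort, and the whole cohort in the panel."""
    params = dict(
        n_founders=40,
        n_generations=8,
        carrying_capacity=300,
        s_lof=0.0, s_mis=0.0,
        n_immigrants=0,
        standing_sites=(60, 300, 600, 1200),
        mu_coding=0.5, mu_noncoding=2.0,
        # informative survival outcome (near 50/50) and effects sized for
        # detection at n = 500 (|z| ~ 2.5 by design); larger litters buffer
        # the higher juvenile mortality demographically
        survival_intercept=-2.9,
        beta_het_survival=16.0,
        het_reference=0.20,
        base_litter=9.0,
        panel_size=None,
    )
    params.update(overrides)
    return SimConfig(seed=seed, **params)


# ---------------------------------------------------------------------------
# internal helpers


def _site_ref_alt(pos: int) -> tuple[str, str]:
    ref = _BASES[pos % 4]
    alt = _BASES[(pos % 4 + 1 + (pos // 4) % 3) % 4]
    return ref, alt


def _site_gene(pos: int, cls: int, genome_length: int) -> str:
    if cls == NONCODING:
        return ""
    span = max(1, genome_length // 250)
    return f"gene{pos // span + 1:04d}"


def _cohort_stats(H: np.ndarray, cls: np.ndarray, genome_length: int) -> dict:
    """Per-individual predictors over sites segregating within the cohort.

    Matches exactly what the load-metrics module recomputes from a VCF of
    this cohort after its complete-call / segregating filters.
    """
    G = H[0::2].astype(np.int16) + H[1::2]
    n = G.shape[0]
    counts = G.sum(axis=0)
    seg = (counts > 0) & (counts < 2 * n)
    scored = seg & (cls != NONCODING)
    denom = max(int(scored.sum()), 1)
    out = {"G": G, "seg": seg, "n_scored": int(scored.sum())}
    for code, key in ((LOF, "e_lof"), (MIS, "e_mis"), (SYN, "e_syn")):
        mask = scored & (cls == code)
        out[key] = (G[:, mask] == 2).sum(axis=1) / denom
    out["het_per_kb"] = (G == 1).sum(axis=1) * 1000.0 / genome_length
    return out


def _viability(G: np.ndarray, cls: np.ndarray, s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Multiplicative viability per individual from genotype counts."""
    logw = np.zeros(G.shape[0])
    for c in (LOF, MIS, SYN):
        if s[c] == 0.0:
            continue
        mask = cls == c
        n_het = (G[:, mask] == 1).sum(axis=1)
        n_hom = (G[:, mask] == 2).sum(axis=1)
        logw = logw + n_het * math.log(max(1.0 - s[c] * h[c], 1e-12))
        logw = logw + n_hom * math.log(max(1.0 - s[c], 1e-12))
    return np.exp(logw)


def _draw_positions(rng: np.random.Generator, n: int, genome_length: int,
                    taken: set[int]) -> np.ndarray:
    """Distinct new lattice positions (infinite-sites)."""
    out: list[int] = []
    while len(out) < n:
        for p in rng.integers(1, genome_length + 1, size=n - len(out)):
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
    return np.array(out, dtype=np.int64)


def _standing_freqs(rng: np.random.Generator, n_sites: int, n_haplotypes: int) -> np.ndarray:
    """Founding derived-allele frequencies from a neutral (1/i) spectrum."""
    i = np.arange(1, n_haplotypes)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / n_haplotypes


@dataclass
class SimulationResult:
    """Everything a downstream analysis needs, in memory.

    ``pedigree``, ``fitness`` and ``litters`` are tidy DataFrames.
    ``variant_table('panel')`` materialises genotypes for the written panel
    (a subsample of the final birth cohort -- the 'resequenced' individuals,
    mixing survivors and dead juveniles, natives and hybrids);
    ``variant_table('juveniles')`` is the entire final birth cohort, whose
    survival outcomes are in ``juvenile_survival``.
    """

    config: SimConfig
    pedigree: pd.DataFrame
    fitness: pd.DataFrame
    litters: pd.DataFrame
    positions: np.ndarray
    classes: np.ndarray
    panel_ids: list[str]
    panel_H: np.ndarray
    juvenile_ids: list[str]
    juvenile_H: np.ndarray
    juvenile_survival: np.ndarray

    def _table(self, ids: list[str], H: np.ndarray) -> VariantTable:
        order = np.argsort(self.positions, kind="stable")
        pos = self.positions[order]
        cls = self.classes[order]
        G = (H[0::2].astype(np.int8) + H[1::2])[:, order]
        cat = {LOF: "LOF", MIS: "MISSENSE", SYN: "SYNONYMOUS", NONCODING: "OTHER"}
        rows = []
        for p, c in zip(pos, cls):
            ref, alt = _site_ref_alt(int(p))
            rows.append(("chr1", int(p), ref, alt, cat[int(c)],
                         _site_gene(int(p), int(c), self.config.genome_length)))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "impact", "gene"])
        return VariantTable(sites=sites, genotypes=G.T, samples=list(ids))

    def variant_table(self, cohort: str = "panel") -> VariantTable:
        if cohort == "panel":
            return self._table(self.panel_ids, self.panel_H)
        if cohort == "juveniles":
            return self._table(self.juvenile_ids, self.juvenile_H)
        raise ValueError(f"unknown cohort {cohort!r}")


def simulate_population(config: SimConfig) -> SimulationResult:
    """Run the forward simulation; see the module docstring for the model.

    Raises :class:`ExtinctionError` if the population dies out (no breeding
    pairs, no cubs, or no surviving juveniles) before ``n_generations``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    s_arr, h_arr = cfg.selection_params()

    taken: set[int] = set()
    pos_blocks: list[np.ndarray] = []
    cls_blocks: list[np.ndarray] = []
    freq_blocks: list[np.ndarray] = []

    n_hap0 = 2 * cfg.n_founders
    for c, n_sites in zip((LOF, MIS, SYN, NONCODING), cfg.standing_sites):
        if n_sites == 0:
            continue
        pos_blocks.append(_draw_positions(rng, n_sites, cfg.genome_length, taken))
        cls_blocks.append(np.full(n_sites, c, dtype=np.int8))
        freq_blocks.append(_standing_freqs(rng, n_sites, n_hap0))
    positions = (np.concatenate(pos_blocks) if pos_blocks
                 else np.empty(0, dtype=np.int64))
    classes = (np.concatenate(cls_blocks) if cls_blocks
               else np.empty(0, dtype=np.int8))
    freqs = np.concatenate(freq_blocks) if freq_blocks else np.empty(0)
    H = (rng.random((n_hap0, len(positions))) < freqs[None, :]).astype(np.uint8)

    ped_rows: list[tuple] = []
    fit_rows: list[dict] = []
    litter_rows: list[tuple] = []
    next_id = 0
    den_effects = rng.normal(0.0, cfg.den_sd, cfg.n_dens)

    def new_ids(k: int) -> list[str]:
        nonlocal next_id
        ids = [f"I{next_id + i:05d}" for i in range(k)]
        next_id += k
        return ids

    def ancestry_label(depth: int) -> str:
        if depth < 0:
            return "native"
        if depth == 0:
            return "immigrant"
        return f"F{min(depth, 4)}"

    def side_type(depth: int) -> str:
        return "native" if depth < 0 else ("immigrant" if depth == 0 else "hybrid")

    def pair_combination(d1: int, d2: int) -> str:
        kinds = sorted((side_type(d1), side_type(d2)))
        if kinds == ["native", "native"]:
            return "native_x_native"
        if kinds == ["immigrant", "native"]:
            return "native_x_immigrant"
        if kinds == ["hybrid", "native"]:
            return "native_x_immigrantF1F4"
        return "immigrantF1F4_x_immigrantF1F4"

    def draw_adult_traits(e_lof: np.ndarray, het: np.ndarray,
                          birth_years: np.ndarray):
        """Longevity, LRS and mean litter size for individuals that reached
        adulthood, from the stated causal model."""
        n = len(e_lof)
        if n == 0:
            empty = np.empty(0)
            return empty, empty.astype(np.int64), empty
        lifespan = (1 + rng.geometric(cfg.adult_stop_prob, n)) * np.exp(
            cfg.beta_lof_longevity * (e_lof - cfg.lof_reference))
        breed_years = np.maximum(np.round(lifespan).astype(int), 1)
        lam0 = cfg.base_litter * np.exp(
            cfg.beta_lof_lrs * (e_lof - cfg.lof_reference)
            + cfg.heterosis_litter * (het - cfg.het_reference))
        lrs = np.zeros(n, dtype=np.int64)
        n_litters = np.zeros(n, dtype=np.int64)
        for t in range(1, int(breed_years.max()) + 1):
            active = breed_years >= t
            if not active.any():
                break
            phases = np.array([cfg.rodent_phase(int(y) + t) for y in birth_years])
            p_breed = np.where(phases == "increase",
                               cfg.breed_prob_increase, cfg.breed_prob_decrease)
            lam_t = lam0 * np.exp(np.where(phases == "decrease",
                                           cfg.litter_phase_decrease, 0.0))
            breeds = active & (rng.random(n) < p_breed)
            cubs = rng.poisson(np.where(breeds, lam_t, 0.0))
            lrs += np.where(breeds, cubs, 0)
            n_litters += breeds.astype(np.int64)
        mean_litter = np.where(n_litters > 0, lrs / np.maximum(n_litters, 1), np.nan)
        return lifespan, lrs, mean_litter

    def fitness_row(iid, sex, depth, den, birth_year, survived,
                    lifespan=np.nan, lrs=np.nan, mean_litter=np.nan) -> dict:
        return dict(
            id=iid,
            sex="F" if sex == 0 else "M",
            ancestry_class=ancestry_label(int(depth)),
            natal_den=den,
            rodent_phase=cfg.rodent_phase(int(birth_year)),
            juvenile_survival=int(survived),
            longevity_years=float(lifespan) if np.isfinite(lifespan) else np.nan,
            lrs=float(lrs) if np.isfinite(lrs) else np.nan,
            mean_litter_size=float(mean_litter) if np.isfinite(mean_litter) else np.nan,
        )

    # founders: native adults born in year 0, balanced sexes
    founder_ids = new_ids(cfg.n_founders)
    founder_sex = np.arange(cfg.n_founders, dtype=np.int64) % 2
    adult_ids = list(founder_ids)
    adult_sex = founder_sex.copy()
    adult_depth = np.full(cfg.n_founders, -1, dtype=np.int64)
    adult_birth = np.zeros(cfg.n_founders, dtype=np.int64)
    for i, iid in enumerate(founder_ids):
        ped_rows.append((iid, "NA", "NA", 0, "native", "NA",
                         "F" if founder_sex[i] == 0 else "M"))
    founder_stats = _cohort_stats(H, classes, cfg.genome_length)
    lifespan, lrs, mean_litter = draw_adult_traits(
        founder_stats["e_lof"], founder_stats["het_per_kb"], adult_birth)
    for i, iid in enumerate(founder_ids):
        fit_rows.append(fitness_row(iid, founder_sex[i], -1, "NA", 0, 1,
                                    lifespan[i], lrs[i], mean_litter[i]))

    juvenile_ids: list[str] = []
    juvenile_H = H[:0, :0].copy()
    juvenile_positions = positions.copy()
    juvenile_classes = classes.copy()
    juvenile_survival = np.empty(0, dtype=np.int64)

    mu_total = cfg.mu_coding + cfg.mu_noncoding
    w_coding = np.asarray(cfg.coding_class_weights, dtype=float)
    w_coding = w_coding / w_coding.sum()
    if mu_total > 0:
        class_p = np.concatenate([w_coding * cfg.mu_coding, [cfg.mu_noncoding]]) / mu_total
    else:
        class_p = np.array([0.0, 0.0, 0.0, 1.0])

    for gen in range(1, cfg.n_generations + 1):
        # --- immigration (arrives before breeding in this year) -------------
        if cfg.n_immigrants > 0 and gen == cfg.immigration_generation:
            n_imm = cfg.n_immigrants
            # outbred source population: Hardy-Weinberg draws from allele
            # frequencies that blend the recipients' with an independent
            # source-population spectrum (divergent subpopulation mix)
            cur_freq = H.mean(axis=0)
            src_freq = _standing_freqs(rng, H.shape[1], 2 * cfg.n_founders)
            d = cfg.immigrant_divergence
            q_imm = (1.0 - d) * cur_freq + d * src_freq
            H_imm = (rng.random((2 * n_imm, H.shape[1]))
                     < q_imm[None, :]).astype(np.uint8)
            div = cfg.immigrant_source_diversity
            if div > 0:
                # novel, source-private variation (incl. HIGH-impact alleles)
                for c, base in zip((LOF, MIS, SYN, NONCODING), cfg.novel_site_base):
                    n_new = int(round(div * base))
                    if n_new == 0:
                        continue
                    newpos = _draw_positions(rng, n_new, cfg.genome_length, taken)
                    newfreq = rng.uniform(0.05, 0.4, n_new)
                    block = (rng.random((2 * n_imm, n_new))
                             < newfreq[None, :]).astype(np.uint8)
                    empty = block.sum(axis=0) == 0
                    if empty.any():
                        carriers = rng.integers(0, 2 * n_imm, int(empty.sum()))
                        block[carriers, np.where(empty)[0]] = 1
                    positions = np.concatenate([positions, newpos])
                    classes = np.concatenate([classes, np.full(n_new, c, dtype=np.int8)])
                    H = np.hstack([H, np.zeros((H.shape[0], n_new), dtype=np.uint8)])
                    H_imm = np.hstack([H_imm, block])
            imm_ids = new_ids(n_imm)
            imm_birth = gen - 1  # born elsewhere, before arrival
            for iid in imm_ids:
                ped_rows.append((iid, "NA", "NA", imm_birth, "immigrant", "NA", "M"))
            H = np.vstack([H, H_imm])
            adult_ids += imm_ids
            adult_sex = np.concatenate([adult_sex, np.ones(n_imm, dtype=np.int64)])
            adult_depth = np.concatenate([adult_depth, np.zeros(n_imm, dtype=np.int64)])
            adult_birth = np.concatenate([adult_birth, np.full(n_imm, imm_birth, dtype=np.int64)])
            imm_stats = _cohort_stats(H, classes, cfg.genome_length)
            sl = slice(len(adult_ids) - n_imm, len(adult_ids))
            lifespan, lrs, mean_litter = draw_adult_traits(
                imm_stats["e_lof"][sl], imm_stats["het_per_kb"][sl], adult_birth[sl])
            for j, iid in enumerate(imm_ids):
                fit_rows.append(fitness_row(iid, 1, 0, "NA", imm_birth, 1,
                                            lifespan[j], lrs[j], mean_litter[j]))

        adult_stats = _cohort_stats(H, classes, cfg.genome_length)

        # --- pair formation --------------------------------------------------
        females = np.where(adult_sex == 0)[0]
        males = np.where(adult_sex == 1)[0]
        rng.shuffle(females)
        rng.shuffle(males)
        # established immigrant males breed with certainty (as documented for
        # released individuals): put them at the head of the male queue
        imm_males = adult_depth[males] == 0
        if imm_males.any():
            males = np.concatenate([males[imm_males], males[~imm_males]])
        n_pairs = min(len(females), len(males))
        if n_pairs == 0:
            raise ExtinctionError(gen)
        dams, sires = females[:n_pairs], males[:n_pairs]
        pair_dens = rng.integers(0, cfg.n_dens, n_pairs)

        # --- litter sizes (pair-level Poisson with heterosis) ----------------
        dosage = adult_stats["G"] / 2.0
        dA, dB = dosage[dams], dosage[sires]
        exp_off_het = ((dA * (1 - dB) + dB * (1 - dA)).sum(axis=1)
                       * 1000.0 / cfg.genome_length)
        pair_e_lof = 0.5 * (adult_stats["e_lof"][dams] + adult_stats["e_lof"][sires])
        phase = cfg.rodent_phase(gen)
        log_lam = (math.log(cfg.base_litter)
                   + (cfg.litter_phase_decrease if phase == "decrease" else 0.0)
                   + den_effects[pair_dens]
                   + cfg.beta_lof_lrs * (pair_e_lof - cfg.lof_reference)
                   + cfg.heterosis_litter * (exp_off_het - cfg.het_reference))
        litter_sizes = rng.poisson(np.exp(log_lam))
        for k in range(n_pairs):
            litter_rows.append((f"den{pair_dens[k]:03d}", gen,
                                pair_combination(int(adult_depth[dams[k]]),
                                                 int(adult_depth[sires[k]])),
                                int(litter_sizes[k])))
        n_cubs = int(litter_sizes.sum())
        if n_cubs == 0:
            raise ExtinctionError(gen)

        # --- meiosis (vectorised over all gametes) ---------------------------
        cub_dam = np.repeat(dams, litter_sizes)
        cub_sire = np.repeat(sires, litter_sizes)
        cub_den = np.repeat(pair_dens, litter_sizes)

        def gametes(parent_idx: np.ndarray) -> np.ndarray:
            a = H[2 * parent_idx]
            b = H[2 * parent_idx + 1]
            cross = rng.integers(1, cfg.genome_length + 1, len(parent_idx))
            start_a = rng.integers(0, 2, len(parent_idx)).astype(bool)[:, None]
            left = positions[None, :] <= cross[:, None]
            first = np.where(start_a, a, b)
            second = np.where(start_a, b, a)
            return np.where(left, first, second)

        H_cubs = np.empty((2 * n_cubs, H.shape[1]), dtype=np.uint8)
        H_cubs[0::2] = gametes(cub_dam)
        H_cubs[1::2] = gametes(cub_sire)

        # --- new mutations ----------------------------------------------------
        n_new = int(rng.poisson(mu_total * n_cubs))
        if n_new > 0:
            newpos = _draw_positions(rng, n_new, cfg.genome_length, taken)
            newcls = rng.choice(4, size=n_new, p=class_p).astype(np.int8)
            hap_idx = rng.integers(0, 2 * n_cubs, n_new)
            block = np.zeros((2 * n_cubs, n_new), dtype=np.uint8)
            block[hap_idx, np.arange(n_new)] = 1
            positions = np.concatenate([positions, newpos])
            classes = np.concatenate([classes, newcls])
            H_cubs = np.hstack([H_cubs, block])

        # --- cub attributes ---------------------------------------------------
        cub_ids = new_ids(n_cubs)
        cub_sex = rng.integers(0, 2, n_cubs)
        cub_depth = np.empty(n_cubs, dtype=np.int64)
        for i in range(n_cubs):
            d1, d2 = int(adult_depth[cub_dam[i]]), int(adult_depth[cub_sire[i]])
            cub_depth[i] = -1 if (d1 < 0 and d2 < 0) else 1 + max(
                d for d in (d1, d2) if d >= 0)
            ped_rows.append((cub_ids[i], adult_ids[cub_dam[i]],
                             adult_ids[cub_sire[i]], gen,
                             ancestry_label(int(cub_depth[i])),
                             f"den{cub_den[i]:03d}",
                             "F" if cub_sex[i] == 0 else "M"))

        # --- juvenile survival and adult traits -------------------------------
        cub_stats = _cohort_stats(H_cubs, classes, cfg.genome_length)
        # soft selection: viability relative to the cohort mean (capped at 1);
        # density regulation is handled separately by the carrying capacity
        w = _viability(cub_stats["G"], classes, s_arr, h_arr)
        w_rel = np.minimum(w / w.mean(), 1.0) if w.mean() > 0 else w
        eta = (cfg.survival_intercept
               + cfg.beta_het_survival * cub_stats["het_per_kb"]
               + cfg.beta_missense_survival * cub_stats["e_mis"])
        p_surv = w_rel / (1.0 + np.exp(-eta))
        survived = rng.random(n_cubs) < p_surv
        surv_idx = np.where(survived)[0]

        birth_years = np.full(len(surv_idx), gen, dtype=np.int64)
        lifespan, lrs, mean_litter = draw_adult_traits(
            cub_stats["e_lof"][surv_idx], cub_stats["het_per_kb"][surv_idx],
            birth_years)
        traits = {int(surv_idx[j]): (lifespan[j], lrs[j], mean_litter[j])
                  for j in range(len(surv_idx))}
        for i in range(n_cubs):
            if survived[i]:
                ls, rr, ml = traits[i]
                fit_rows.append(fitness_row(cub_ids[i], cub_sex[i], cub_depth[i],
                                            f"den{cub_den[i]:03d}", gen, 1,
                                            ls, rr, ml))
            else:
                fit_rows.append(fitness_row(cub_ids[i], cub_sex[i], cub_depth[i],
                                            f"den{cub_den[i]:03d}", gen, 0))

        if gen == cfg.n_generations:
            juvenile_ids = list(cub_ids)
            juvenile_H = H_cubs.copy()
            juvenile_positions = positions.copy()
            juvenile_classes = classes.copy()
            juvenile_survival = survived.astype(np.int64)
            break  # site pruning below would drop cub-only alleles

        if len(surv_idx) == 0:
            raise ExtinctionError(gen)
        if len(surv_idx) > cfg.carrying_capacity:
            keep = rng.choice(len(surv_idx), cfg.carrying_capacity, replace=False)
            keep.sort()
            surv_idx = surv_idx[keep]

        rows = np.empty(2 * len(surv_idx), dtype=np.int64)
        rows[0::2] = 2 * surv_idx
        rows[1::2] = 2 * surv_idx + 1
        H = H_cubs[rows]
        adult_ids = [cub_ids[i] for i in surv_idx]
        adult_sex = cub_sex[surv_idx]
        adult_depth = cub_depth[surv_idx]
        adult_birth = np.full(len(surv_idx), gen, dtype=np.int64)

        # prune sites lost from the breeding population
        alive = H.sum(axis=0) > 0
        H = H[:, alive]
        positions = positions[alive]
        classes = classes[alive]

    # --- final panel -----------------------------------------------------------
    if cfg.n_generations == 0:
        juvenile_ids, juvenile_H = [], H[:0, :0].copy()
        juvenile_positions, juvenile_classes = positions.copy(), classes.copy()
        juvenile_survival = np.empty(0, dtype=np.int64)
        pool_ids, pool_H = list(founder_ids), H
    else:
        pool_ids, pool_H = juvenile_ids, juvenile_H

    n_pool = len(pool_ids)
    if cfg.panel_size is not None and cfg.panel_size < n_pool:
        # stratified panel: the study design deliberately samples both
        # natives and immigrant descendants where both exist
        ped_anc = {r[0]: r[4] for r in ped_rows}
        is_native = np.array([ped_anc[i] == "native" for i in pool_ids])
        nat_idx = np.where(is_native)[0]
        hyb_idx = np.where(~is_native)[0]
        half = cfg.panel_size // 2
        n_nat = min(len(nat_idx), max(half, cfg.panel_size - len(hyb_idx)))
        n_hyb = min(len(hyb_idx), cfg.panel_size - n_nat)
        n_nat = cfg.panel_size - n_hyb
        parts = []
        if n_nat > 0:
            parts.append(rng.choice(nat_idx, n_nat, replace=False))
        if n_hyb > 0:
            parts.append(rng.choice(hyb_idx, n_hyb, replace=False))
        pick = np.sort(np.concatenate(parts))
    else:
        pick = np.arange(n_pool)
    panel_ids = [pool_ids[i] for i in pick]
    rows = np.empty(2 * len(pick), dtype=np.int64)
    rows[0::2] = 2 * pick
    rows[1::2] = 2 * pick + 1
    panel_H = pool_H[rows].copy()

    pedigree = pd.DataFrame(
        ped_rows, columns=["id", "dam", "sire", "birth_year", "ancestry_class",
                           "natal_den", "sex"])
    fitness = pd.DataFrame(fit_rows)[
        ["id", "sex", "ancestry_class", "natal_den", "rodent_phase",
         "juvenile_survival", "longevity_years", "lrs", "mean_litter_size"]]
    litters = pd.DataFrame(litter_rows,
                           columns=["den", "year", "pair_combination", "litter_size"])

    return SimulationResult(
        config=cfg, pedigree=pedigree, fitness=fitness, litters=litters,
        positions=juvenile_positions, classes=juvenile_classes,
        panel_ids=panel_ids, panel_H=panel_H,
        juvenile_ids=list(juvenile_ids), juvenile_H=juvenile_H,
        juvenile_survival=juvenile_survival,
    )


# ---------------------------------------------------------------------------
# output writers


def _vcf_lines(result: SimulationResult, cohort: str = "panel"):
    table = result.variant_table(cohort)
    cfg = result.config
    yield "##fileformat=VCFv4.2"
    yield f"##contig=<ID=chr1,length={cfg.genome_length}>"
    yield ('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
           "annotations: 'Allele | Annotation | Annotation_Impact | "
           "Gene_Name | Gene_ID'\">")
    yield ('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    yield ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
           + "\t".join(table.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    cat_to_ann = {"LOF": ("stop_gained", "HIGH"),
                  "MISSENSE": ("missense_variant", "MODERATE"),
                  "SYNONYMOUS": ("synonymous_variant", "LOW"),
                  "OTHER": ("intergenic_region", "MODIFIER")}
    for i, site in table.sites.iterrows():
        term, impact = cat_to_ann[site["impact"]]
        gene = site["gene"] or "."
        ann = f"ANN={site['alt']}|{term}|{impact}|{gene}|{gene}"
        gts = "\t".join(gt_str[int(v)] for v in table.genotypes[i])
        yield (f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t{site['alt']}"
               f"\t.\tPASS\t{ann}\tGT\t{gts}")


def write_outputs(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, pedigree TSV, fitness/metadata TSV and litter TSV.

    Deterministic: a fixed seed produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "sim.vcf",
        "pedigree": out / "pedigree.tsv",
        "fitness": out / "fitness.tsv",
        "litters": out / "litters.tsv",
    }
    with open(paths["vcf"], "w") as fh:
        for line in _vcf_lines(result):
            fh.write(line + "\n")
    result.pedigree.to_csv(paths["pedigree"], sep="\t", index=False, na_rep="NA")
    fitness = result.fitness.copy()
    fitness["longevity_years"] = fitness["longevity_years"].round(4)
    fitness["mean_litter_size"] = fitness["mean_litter_size"].round(4)
    fitness.to_csv(paths["fitness"], sep="\t", index=False, na_rep="NA")
    result.litters.to_csv(paths["litters"], sep="\t", index=False, na_rep="NA")
    return paths
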