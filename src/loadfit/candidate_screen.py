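"""Zygosity-pattern screens for candidate LoF variants and enrichment tests.

Three screens over a filtered, annotated variant table:

* ``hybrid_private_lofs`` -- LoF variants absent from the native gene pool
  with derived-allele frequency at or above a threshold (default 20%) among
  immigrant descendants;
* ``litter_size_screen`` -- LoF variants carried (het or hom) by every
  low-fecundity individual and never homozygous in high-fecundity ones;
* ``longevity_screen`` -- LoF variants homozygous in (a fraction of) the
  short-lived individuals and never homozygous in the long-lived ones.

Plus a generic overrepresentation test of candidate genes against a
gene -> term map: one-sided Fisher's exact (hypergeometric tail) p per term
with Bonferroni correction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .load_metrics import ImpactCategory, VariantTable, HOM_ALT

__all__ = [
    "hybrid_private_lofs",
    "litter_size_screen",
    "longevity_screen",
    "fisher_enrichment_p",
    "overrepresentation_test",
]


def fisher_enrichment_p(overlap: int, n_universe: int, n_term: int,
                        n_candidates: int) -> float:
    """One-sided Fisher's exact p for enrichment: the hypergeometric upper
    tail P(X >= overlap) with X ~ Hypergeom(N=n_universe, K=n_term,
    n=n_candidates)."""
    return float(sps.hypergeom.sf(overlap - 1, n_universe, n_term, n_candidates))


def _indices(table: VariantTable, ids: Iterable[str]) -> list[int]:
    return [table.sample_index(i) for i in ids]


def _check_groups(a: Sequence[str], b: Sequence[str]) -> None:
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")


def hybrid_private_lofs(table: VariantTable, native_ids: Sequence[str],
                        hybrid_ids: Sequence[str],
                        freq_threshold: float = 0.20) -> pd.DataFrame:
    """LoF variants absent in natives with hybrid allele frequency >=
    ``freq_threshold`` (inclusive), sorted by frequency descending.

    Frequency is the derived-allele frequency over hybrid chromosomes
    (2 x n individuals), reported as percent.
    """
    _check_groups(native_ids, hybrid_ids)
    if not 0.0 <= freq_threshold <= 1.0:
        raise ValueError("freq_threshold must be in [0, 1]")
    lof = table.class_mask(ImpactCategory.LOF)
    g = table.genotypes[lof]
    sites = table.sites.loc[lof].reset_index(drop=True)
    gi_nat = g[:, _indices(table, native_ids)]
    gi_hyb = g[:, _indices(table, hybrid_ids)]
    absent_native = (np.where(gi_nat > 0, gi_nat, 0).sum(axis=1) == 0)
    freq = np.where(gi_hyb > 0, gi_hyb, 0).sum(axis=1) / (2.0 * len(hybrid_ids))
    keep = absent_native & (freq >= freq_threshold)
    out = sites.loc[keep, ["chrom", "pos", "gene"]].copy()
    out["hybrid_freq_percent"] = 100.0 * freq[keep]
    return out.sort_values("hybrid_freq_percent", ascending=False,
                           kind="stable").reset_index(drop=True)


def litter_size_screen(table: VariantTable, low_group: Sequence[str],
                       high_group: Sequence[str]) -> pd.DataFrame:
    """LoF variants consistent with a recessive effect on litter size.

    A site passes iff (i) every low-fecundity individual carries at least
    one derived allele (hom or het, never absent) and (ii) no high-fecundity
    individual is homozygous for the derived allele. The output reports the
    fraction of low-group individuals that are homozygous.
    """
    _check_groups(low_group, high_group)
    lof = table.class_mask(ImpactCategory.LOF)
    g = table.genotypes[lof]
    sites = table.sites.loc[lof].reset_index(drop=True)
    g_low = g[:, _indices(table, low_group)]
    g_high = g[:, _indices(table, high_group)]
    all_low_carry = (g_low > 0).all(axis=1)
    no_high_hom = ~(g_high == HOM_ALT).any(axis=1)
    keep = all_low_carry & no_high_hom
    out = sites.loc[keep, ["chrom", "pos", "gene"]].copy()
    out["low_hom_fraction"] = (g_low[keep] == HOM_ALT).mean(axis=1)
    return out.sort_values("low_hom_fraction", ascending=False,
                           kind="stable").reset_index(drop=True)


def longevity_screen(table: VariantTable, short_group: Sequence[str],
                     long_group: Sequence[str],
                     min_hom_fraction: float = 1.0) -> pd.DataFrame:
    """LoF variants consistent with a recessive effect on lifespan.

    A site passes iff (i) no long-lived individual is homozygous for the
    derived allele and (ii) the fraction of short-lived individuals that are
    homozygous is >= ``min_hom_fraction``. The default 1.0 is the strict
    all-homozygous rule; 0.4 reproduces the relaxed at-least-40% report.
    """
    _check_groups(short_group, long_group)
    if not 0.0 <= min_hom_fraction <= 1.0:
        raise ValueError("min_hom_fraction must be in [0, 1]")
    lof = table.class_mask(ImpactCategory.LOF)
    g = table.genotypes[lof]
    sites = table.sites.loc[lof].reset_index(drop=True)
    g_short = g[:, _indices(table, short_group)]
    g_long = g[:, _indices(table, long_group)]
    hom_frac = (g_short == HOM_ALT).mean(axis=1)
    no_long_hom = ~(g_long == HOM_ALT).any(axis=1)
    keep = no_long_hom & (hom_frac >= min_hom_fraction)
    out = sites.loc[keep, ["chrom", "pos", "gene"]].copy()
    out["short_hom_fraction"] = hom_frac[keep]
    return out.sort_values("short_hom_fraction", ascending=False,
                           kind="stable").reset_index(drop=True)


def overrepresentation_test(candidate_genes: Iterable[str],
                            universe_genes: Iterable[str],
                            term_map: Mapping[str, Iterable[str]] | pd.DataFrame,
                            skip_empty_terms: bool = True,
                            bonferroni_all_terms: bool = False) -> pd.DataFrame:
    """Per-term enrichment of candidate genes by one-sided Fisher's exact test.

    ``term_map`` maps gene -> term ids (or a two-column DataFrame
    ``gene, term``). For each term the 2x2 table is
    (candidate & term, candidate & ~term; rest & term, rest & ~term) and the
    one-sided p is the hypergeometric upper tail P(X >= overlap). Terms with
    zero candidate hits are skipped from testing by default but can be
    counted in the Bonferroni denominator via ``bonferroni_all_terms``.
    """
    universe = sorted(set(universe_genes))
    if not universe:
        raise ValueError("empty gene universe")
    candidates = sorted(set(candidate_genes))
    stray = set(candidates) - set(universe)
    if stray:
        raise ValueError(f"candidate genes outside the universe: {sorted(stray)}")

    if isinstance(term_map, pd.DataFrame):
        pairs = term_map.iloc[:, :2].itertuples(index=False)
        mapping: dict[str, set[str]] = {}
        for gene, term in pairs:
            mapping.setdefault(str(gene), set()).add(str(term))
        term_map = mapping
    terms: dict[str, set[str]] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):  # type: ignore[union-attr]
            terms.setdefault(str(term), set()).add(gene)

    n_univ = len(universe)
    n_cand = len(candidates)
    cand_set = set(candidates)
    rows = []
    for term, genes in sorted(terms.items()):
        k_term = len(genes)
        overlap = len(genes & cand_set)
        rows.append((term, k_term, overlap))
    n_all = len(rows)
    tested = [(t, k, o) for t, k, o in rows if o > 0 or not skip_empty_terms]
    denom = n_all if bonferroni_all_terms else max(len(tested), 1)

    out = []
    for term, k_term, overlap in tested:
        p = fisher_enrichment_p(overlap, n_univ, k_term, n_cand)
        out.append(dict(
            term=term,
            n_term=k_term,
            n_candidates=n_cand,
            overlap=overlap,
            candidate_not_term=n_cand - overlap,
            rest_term=k_term - overlap,
            rest_not_term=n_univ - n_cand - (k_term - overlap),
            p=p,
            p_bonferroni=min(1.0, p * denom),
        ))
    df = pd.DataFrame(out, columns=["term", "n_term", "n_candidates", "overlap",
                                    "candidate_not_term", "rest_term",
                                    "rest_not_term", "p", "p_bonferroni"])
    return df.sort_values("p", kind="stable").reset_index(drop=True)
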