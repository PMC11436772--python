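"""Per-individual mutational-load statistics from an impact-annotated VCF.

This module reads a multi-sample diploid VCF whose INFO field carries
SnpEff-style ``ANN`` annotations, applies the study's site filters (complete
calls in every individual; fixed and monomorphic sites removed) and computes:

* allele-level load: the proportion of an individual's derived alleles that
  fall in each impact class (LoF, missense, synonymous);
* genotype-level load: the proportion of scored sites at which the individual
  is homozygous for the derived allele ("expressed" load) or heterozygous
  ("masked" load), per impact class;
* genome-wide heterozygosity as heterozygous sites per 1 kb of callable
  sequence;
* per-class unfolded site-frequency spectra;
* gene-pool LoF summaries contrasting two groups of individuals
  (e.g. natives vs immigrant descendants).

The ALT allele is treated as the derived allele throughout; this is an
explicit assumption, recorded in the docs, not an inference from outgroup
polarisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImpactCategory",
    "VariantTable",
    "LoadProfile",
    "SFS",
    "GenePoolSummary",
    "read_annotated_vcf",
    "apply_site_filters",
    "compute_load_profile",
    "compute_load_profiles",
    "compute_sfs",
    "heterozygosity_per_kb",
    "gene_pool_lof_summary",
    "percent_excess",
    "write_load_profiles",
]

# genotype codes in VariantTable.genotypes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

LOAD_PROFILE_COLUMNS = [
    "id", "n_sites_scored",
    "p_lof", "p_mis", "p_syn",
    "e_lof", "e_mis", "e_syn",
    "m_lof", "m_mis", "m_syn",
    "het_per_kb",
]


class ImpactCategory(str, Enum):
    """Functional impact class of a coding variant.

    SnpEff annotation impacts map as HIGH -> LOF (putative loss of function,
    e.g. stop gained), MODERATE -> MISSENSE, LOW -> SYNONYMOUS. Everything
    else (MODIFIER, unparseable or absent annotations) is OTHER and is
    excluded from load denominators but still counted for heterozygosity.
    """

    LOF = "LOF"
    MISSENSE = "MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


_IMPACT_TO_CATEGORY = {
    "HIGH": ImpactCategory.LOF,
    "MODERATE": ImpactCategory.MISSENSE,
    "LOW": ImpactCategory.SYNONYMOUS,
}

_LOAD_CLASSES = (ImpactCategory.LOF, ImpactCategory.MISSENSE, ImpactCategory.SYNONYMOUS)
_CLASS_SUFFIX = {ImpactCategory.LOF: "lof", ImpactCategory.MISSENSE: "mis",
                 ImpactCategory.SYNONYMOUS: "syn"}


@dataclass
class VariantTable:
    """Biallelic site records plus a genotype matrix.

    ``sites`` has one row per (split) biallelic record with columns
    ``chrom, pos, ref, alt, impact, gene``; ``genotypes`` is an int8 array of
    shape (n_sites, n_samples) coded 0=hom_ref, 1=het, 2=hom_alt, -1=missing.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, individual: str) -> int:
        try:
            return self.samples.index(individual)
        except ValueError:
            raise KeyError(f"unknown sample {individual!r}") from None

    def class_mask(self, category: ImpactCategory) -> np.ndarray:
        return (self.sites["impact"].to_numpy() == category.value)

    def subset_sites(self, keep: np.ndarray) -> "VariantTable":
        return VariantTable(
            sites=self.sites.loc[keep].reset_index(drop=True),
            genotypes=self.genotypes[keep],
            samples=list(self.samples),
        )


@dataclass
class LoadProfile:
    """Per-individual load summary.

    Allele-level proportions (``p_*``) partition the individual's derived
    alleles among the three impact classes and sum to 1 when defined (NaN if
    the individual carries no derived allele at scored sites). Genotype-level
    proportions use ``n_sites_scored`` as denominator: ``e_*`` counts
    homozygous-derived genotypes (expressed load), ``m_*`` heterozygous ones
    (masked load).
    """

    id: str
    n_sites_scored: int
    p_lof: float
    p_mis: float
    p_syn: float
    e_lof: float
    e_mis: float
    e_syn: float
    m_lof: float
    m_mis: float
    m_syn: float
    het_per_kb: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in LOAD_PROFILE_COLUMNS}


@dataclass
class SFS:
    """Unfolded site-frequency spectrum for one impact class.

    ``counts[i - 1]`` is the number of segregating sites whose derived-allele
    count equals ``i`` (i = 1 .. 2N-1) among ``n_individuals`` diploids.
    """

    category: ImpactCategory
    counts: np.ndarray
    n_individuals: int

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    @property
    def mean_derived_frequency(self) -> float:
        """Mean derived-allele frequency over segregating sites (NaN if none)."""
        total = self.counts.sum()
        if total == 0:
            return float("nan")
        i = np.arange(1, len(self.counts) + 1)
        return float((i * self.counts).sum() / (total * 2 * self.n_individuals))


@dataclass
class GenePoolSummary:
    """LoF gene-pool contrast between two groups.

    A LoF site belongs to a group's gene pool if at least one member carries
    at least one derived allele. ``percent_excess`` is the percent by which
    group B's pool exceeds group A's, to one decimal.
    """

    group_a: str
    group_b: str
    n_lof_a: int
    n_lof_b: int
    private_a: int
    private_b: int
    percent_excess: float


def _parse_ann(ann_value: str | None, alt: str) -> tuple[ImpactCategory, str]:
    """Return (category, gene) for one ALT allele from an ANN INFO string.

    The SnpEff dialect is ``Allele|Annotation|Annotation_Impact|Gene_Name|...``
    with one comma-separated entry per allele; only fields 1-4 are consumed.
    """
    if not ann_value:
        return ImpactCategory.OTHER, ""
    for entry in str(ann_value).split(","):
        fields = entry.split("|")
        if len(fields) < 3:
            continue
        if fields[0] != alt:
            continue
        category = _IMPACT_TO_CATEGORY.get(fields[2].strip(), ImpactCategory.OTHER)
        gene = fields[3].strip() if len(fields) > 3 else ""
        return category, gene
    return ImpactCategory.OTHER, ""


def read_annotated_vcf(path: str | Path,
                       required_samples: Sequence[str] | None = None) -> VariantTable:
    """Read a VCF v4.2 (+.gz) with ANN-style annotations into a VariantTable.

    Multiallelic records are split into one biallelic record per ALT allele,
    each carrying the ANN entry whose Allele field matches that ALT. Records
    without a parseable matching annotation are kept with category OTHER and
    a warning (never silently dropped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if required_samples is not None:
        missing = [s for s in required_samples if s not in samples]
        if missing:
            raise ValueError(f"samples missing from VCF: {missing}")

    rows: list[tuple] = []
    geno_rows: list[np.ndarray] = []
    n_unannotated = 0
    for variant in vcf:
        ann = variant.INFO.get("ANN")
        gts = np.asarray(variant.genotypes, dtype=np.int64)
        if gts.size == 0:
            a1 = a2 = np.zeros(len(samples), dtype=np.int64)
        else:
            a1, a2 = gts[:, 0], gts[:, 1]
        for k, alt in enumerate(variant.ALT):
            allele_num = k + 1
            code = (a1 == allele_num).astype(np.int8) + (a2 == allele_num).astype(np.int8)
            code[(a1 < 0) | (a2 < 0)] = MISSING
            category, gene = _parse_ann(ann, alt)
            if category is ImpactCategory.OTHER and ann is None:
                n_unannotated += 1
            rows.append((variant.CHROM, variant.POS, variant.REF, alt,
                         category.value, gene))
            geno_rows.append(code)
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} site(s) lacked a parseable ANN annotation; "
            "categorised as OTHER", stacklevel=2)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "impact", "gene"])
    genotypes = (np.vstack(geno_rows) if geno_rows
                 else np.empty((0, len(samples)), dtype=np.int8))
    return VariantTable(sites=sites, genotypes=genotypes, samples=samples)


def apply_site_filters(table: VariantTable) -> tuple[VariantTable, dict]:
    """Retain complete-call, segregating sites.

    A site is removed if (a) any individual has a missing genotype, or
    (b) it is fixed (every individual hom_alt) or monomorphic for the
    reference (no individual carries the derived allele). Returns the
    filtered table and removal counts per rule.
    """
    g = table.genotypes
    n = table.n_samples
    complete = (g != MISSING).all(axis=1) if n else np.ones(len(g), dtype=bool)
    alt_count = np.where(g == MISSING, 0, g).sum(axis=1)
    fixed = complete & (g == HOM_ALT).all(axis=1) if len(g) else complete
    mono_ref = complete & (alt_count == 0)
    keep = complete & ~fixed & ~mono_ref
    removed = {
        "missing": int((~complete).sum()),
        "fixed": int(fixed.sum()),
        "monomorphic_ref": int(mono_ref.sum()),
    }
    return table.subset_sites(keep), removed


def _load_class_masks(table: VariantTable) -> dict[ImpactCategory, np.ndarray]:
    return {c: table.class_mask(c) for c in _LOAD_CLASSES}


def compute_load_profiles(table: VariantTable,
                          callable_length_bp: float,
                          denominator: str = "all_sites") -> pd.DataFrame:
    """Load profiles for every sample in a filtered table.

    ``denominator`` selects the genotype-level load denominator:
    ``all_sites`` (default) uses every retained LoF+missense+synonymous site,
    which the complete-call filter makes constant across individuals;
    ``carrier_sites`` uses only sites where the individual carries at least
    one derived allele.
    """
    if callable_length_bp <= 0:
        raise ValueError("callable_length_bp must be > 0")
    if denominator not in ("all_sites", "carrier_sites"):
        raise ValueError(f"unknown load denominator {denominator!r}")

    g = table.genotypes
    masks = _load_class_masks(table)
    scored = np.zeros(table.n_sites, dtype=bool)
    for m in masks.values():
        scored |= m
    n_scored = int(scored.sum())

    records = []
    for j, sample in enumerate(table.samples):
        gj = g[:, j]
        derived = np.where(gj > 0, gj, 0)
        total_derived = int(derived[scored].sum())
        row: dict = {"id": sample, "n_sites_scored": n_scored}
        if total_derived == 0:
            warnings.warn(
                f"individual {sample!r} carries no derived allele at scored "
                "sites; allele-load proportions undefined", stacklevel=2)
        if denominator == "all_sites":
            denom_geno = n_scored
        else:
            denom_geno = int((gj[scored] > 0).sum())
        for cat, mask in masks.items():
            suffix = _CLASS_SUFFIX[cat]
            n_alleles = int(derived[mask].sum())
            n_hom = int((gj[mask] == HOM_ALT).sum())
            n_het = int((gj[mask] == HET).sum())
            row[f"p_{suffix}"] = (n_alleles / total_derived
                                  if total_derived else float("nan"))
            row[f"e_{suffix}"] = n_hom / denom_geno if denom_geno else float("nan")
            row[f"m_{suffix}"] = n_het / denom_geno if denom_geno else float("nan")
        row["het_per_kb"] = float((gj == HET).sum()) * 1000.0 / callable_length_bp
        records.append(row)
    return pd.DataFrame(records, columns=LOAD_PROFILE_COLUMNS)


def compute_load_profile(table: VariantTable, individual: str,
                         callable_length_bp: float,
                         denominator: str = "all_sites") -> LoadProfile:
    """Load profile for a single individual (see :func:`compute_load_profiles`)."""
    df = compute_load_profiles(table, callable_length_bp, denominator)
    row = df.loc[df["id"] == individual]
    if row.empty:
        raise KeyError(f"unknown sample {individual!r}")
    return LoadProfile(**row.iloc[0].to_dict())


def compute_sfs(table: VariantTable, category: ImpactCategory) -> SFS:
    """Unfolded SFS: derived-allele counts tallied into bins 1 .. 2N-1.

    Sites of other categories, and (defensively) non-segregating counts, are
    ignored; a category with zero sites yields an all-zero spectrum.
    """
    n = table.n_samples
    counts = np.zeros(max(2 * n - 1, 0), dtype=np.int64)
    mask = table.class_mask(category)
    if mask.any():
        g = table.genotypes[mask]
        derived = np.where(g == MISSING, 0, g).sum(axis=1)
        derived = derived[(derived >= 1) & (derived <= 2 * n - 1)]
        binned = np.bincount(derived, minlength=2 * n)
        counts = binned[1:2 * n]
    return SFS(category=category, counts=counts, n_individuals=n)


def heterozygosity_per_kb(table: VariantTable, individual: str,
                          callable_length_bp: float) -> float:
    """Heterozygous sites per 1 kb of callable sequence, over all site classes."""
    if callable_length_bp <= 0:
        raise ValueError("callable_length_bp must be > 0")
    j = table.sample_index(individual)
    n_het = int((table.genotypes[:, j] == HET).sum())
    return n_het * 1000.0 / callable_length_bp


def percent_excess(n_a: int, n_b: int) -> float:
    """Percent by which count B exceeds count A, to one decimal."""
    if n_a <= 0:
        raise ValueError("reference count must be positive")
    return round(100.0 * (n_b - n_a) / n_a, 1)


def gene_pool_lof_summary(table: VariantTable,
                          groups: Mapping[str, Iterable[str]]) -> GenePoolSummary:
    """Contrast the LoF gene pools of two groups of individuals.

    ``groups`` maps exactly two group names to member sample ids; the first
    group is the reference (A) for the percent-excess computation.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    ids_a, ids_b = list(ids_a), list(ids_b)
    if not ids_a or not ids_b:
        raise ValueError("both groups must be non-empty")

    lof = table.class_mask(ImpactCategory.LOF)
    g = table.genotypes[lof]
    idx_a = [table.sample_index(s) for s in ids_a]
    idx_b = [table.sample_index(s) for s in ids_b]
    in_a = (g[:, idx_a] > 0).any(axis=1)
    in_b = (g[:, idx_b] > 0).any(axis=1)
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    return GenePoolSummary(
        group_a=name_a, group_b=name_b,
        n_lof_a=n_a, n_lof_b=n_b,
        private_a=int((in_a & ~in_b).sum()),
        private_b=int((in_b & ~in_a).sum()),
        percent_excess=percent_excess(n_a, n_b),
    )


def write_load_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_sfs(sfs: SFS, path: str | Path) -> None:
    df = pd.DataFrame({
        "derived_count": np.arange(1, len(sfs.counts) + 1),
        "n_sites": sfs.counts,
        "proportion": sfs.proportions,
    })
    df.to_csv(path, sep="\t", index=False)
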