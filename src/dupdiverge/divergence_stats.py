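"""Statistical layer linking structural, sequence and expression divergence.

* Group comparison: transformed r of structurally divergent (SD) vs
  non-structurally-divergent (NSD) pairs, overall and within the
  species-specific subset, by two-sided Wilcoxon rank-sum (exact for small
  groups).  Lower transformed r means higher expression divergence.
* ANCOVA: common-slope linear model transformed_r ~ dS + SD indicator; the
  indicator coefficient is the structure effect controlling for synonymous
  divergence.  Per-class OLS lines are fit alongside.
* Identity distributions: Wilcoxon rank-sum and Kolmogorov–Smirnov
  comparisons of pair identities (species-specific vs all, intra- vs
  interchromosomal), with 5%-bin histograms.
* Chromosome distribution: chi-square heterogeneity of duplicate-gene
  counts against expectation proportional to gene counts, plus per-
  chromosome exact binomial tests of the intra fraction against the
  genome-wide intra fraction.

Genome-scale analyses use these tests ordinally (significant or not);
no multiple-testing correction is applied by default, but a
Benjamini–Hochberg helper is provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dup_identify import ChromosomeSummary, DuplicatePair
from .expression_divergence import ExpressionComparison
from .structure_divergence import StructureComparison

__all__ = [
    "GroupComparison",
    "AncovaResult",
    "compare_sd_nsd",
    "ancova_structure_expression",
    "identity_distribution_tests",
    "chromosome_distribution_test",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    median: float


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    statistic: float
    p_value: float


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[GroupStats, ...]
    contrasts: tuple[Contrast, ...]


@dataclass(frozen=True)
class AncovaResult:
    """Common-slope ANCOVA of transformed r on dS with an SD indicator."""

    structure_coef: float
    structure_p: float
    structure_se: float
    ds_coef: float
    ds_p: float
    intercept: float
    r_squared: float
    n_sd: int
    n_nsd: int
    # per-class simple regressions (slope, intercept) of transformed_r on dS
    line_sd: tuple[float, float]
    line_nsd: tuple[float, float]


def _group_stats(label: str, values: np.ndarray) -> GroupStats:
    return GroupStats(
        label=label,
        n=len(values),
        mean=float(np.mean(values)) if len(values) else float("nan"),
        median=float(np.median(values)) if len(values) else float("nan"),
    )


def _paired_rows(comparisons: Sequence[ExpressionComparison],
                 structures: Sequence[StructureComparison]) -> list[tuple[ExpressionComparison, StructureComparison]]:
    by_key = {(s.gene_a, s.gene_b): s for s in structures}
    rows = []
    for c in comparisons:
        s = by_key.get((c.gene_a, c.gene_b)) or by_key.get((c.gene_b, c.gene_a))
        if s is None:
            raise KeyError(f"no structure comparison for pair ({c.gene_a}, {c.gene_b})")
        rows.append((c, s))
    return rows


def compare_sd_nsd(comparisons: Sequence[ExpressionComparison],
                   structures: Sequence[StructureComparison],
                   lineage: Mapping[tuple[str, str], str] | None = None) -> GroupComparison:
    """Wilcoxon rank-sum of transformed r between SD and NSD pairs.

    Uses eligible pairs with defined transformed r.  With a lineage mapping,
    the SD vs NSD contrast is additionally run within species-specific
    pairs.  Empty groups skip their contrast with a warning.  The exact
    null distribution is used when both groups have ≤ 25 observations and
    no ties.
    """
    rows = [
        (c, s) for c, s in _paired_rows(comparisons, structures)
        if c.eligible and math.isfinite(c.transformed_r)
    ]
    sd = np.array([c.transformed_r for c, s in rows if s.divergent])
    nsd = np.array([c.transformed_r for c, s in rows if not s.divergent])
    groups = [_group_stats("NSD", nsd), _group_stats("SD", sd)]
    contrasts: list[Contrast] = []

    def add_contrast(name_a: str, a: np.ndarray, name_b: str, b: np.ndarray) -> None:
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"empty group in contrast {name_a} vs {name_b}; skipped", stacklevel=3)
            return
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if max(len(a), len(b)) <= 25 else "asymptotic")
        contrasts.append(Contrast(name_a, name_b, float(res.statistic), float(res.pvalue)))

    add_contrast("NSD", nsd, "SD", sd)
    if lineage is not None:
        spec = [
            (c, s) for c, s in rows
            if lineage.get((c.gene_a, c.gene_b)) == "species_specific"
        ]
        sd_s = np.array([c.transformed_r for c, s in spec if s.divergent])
        nsd_s = np.array([c.transformed_r for c, s in spec if not s.divergent])
        groups += [
            _group_stats("NSD species_specific", nsd_s),
            _group_stats("SD species_specific", sd_s),
        ]
        add_contrast("NSD species_specific", nsd_s, "SD species_specific", sd_s)
    return GroupComparison(groups=tuple(groups), contrasts=tuple(contrasts))


def ancova_structure_expression(comparisons: Sequence[ExpressionComparison],
                                structures: Sequence[StructureComparison],
                                ds_values: Mapping[tuple[str, str], float],
                                interaction: bool = False) -> AncovaResult:
    """Fit transformed_r ~ dS + SD indicator (+ optional interaction).

    Eligible pairs with finite transformed r and finite dS only.  The SD
    indicator's coefficient is the structure effect on expression
    similarity controlling for synonymous divergence.  Raises on a
    single-class (rank-deficient) design.
    """
    y, x_ds, x_sd = [], [], []
    for c, s in _paired_rows(comparisons, structures):
        ds = ds_values.get((c.gene_a, c.gene_b), ds_values.get((c.gene_b, c.gene_a)))
        if ds is None or not math.isfinite(ds):
            continue
        if not (c.eligible and math.isfinite(c.transformed_r)):
            continue
        y.append(c.transformed_r)
        x_ds.append(ds)
        x_sd.append(1.0 if s.divergent else 0.0)
    y_arr = np.asarray(y)
    ds_arr = np.asarray(x_ds)
    sd_arr = np.asarray(x_sd)
    n_sd = int(sd_arr.sum())
    n_nsd = len(sd_arr) - n_sd
    if n_sd == 0 or n_nsd == 0:
        raise ValueError("ANCOVA design is rank-deficient: only one structural class present")
    cols = {"dS": ds_arr, "SD": sd_arr}
    if interaction:
        cols["dS:SD"] = ds_arr * sd_arr
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(y_arr, X).fit()

    def line(mask: np.ndarray) -> tuple[float, float]:
        if mask.sum() < 2 or np.ptp(ds_arr[mask]) == 0.0:
            return float("nan"), float("nan")
        res = stats.linregress(ds_arr[mask], y_arr[mask])
        return float(res.slope), float(res.intercept)

    return AncovaResult(
        structure_coef=float(fit.params["SD"]),
        structure_p=float(fit.pvalues["SD"]),
        structure_se=float(fit.bse["SD"]),
        ds_coef=float(fit.params["dS"]),
        ds_p=float(fit.pvalues["dS"]),
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        n_sd=n_sd,
        n_nsd=n_nsd,
        line_sd=line(sd_arr == 1.0),
        line_nsd=line(sd_arr == 0.0),
    )


def identity_distribution_tests(pairs: Sequence[DuplicatePair],
                                bin_width: float = 0.05) -> dict:
    """Compare identity distributions: species-specific vs all, intra vs inter.

    Each comparison reports a two-sided Wilcoxon rank-sum and a two-sample
    Kolmogorov–Smirnov test; histograms use ``bin_width`` identity bins.
    """
    all_ids = np.array([p.identity for p in pairs])
    specific = np.array([p.identity for p in pairs if p.lineage == "species_specific"])
    intra = np.array([p.identity for p in pairs if p.locality == "intra"])
    inter = np.array([p.identity for p in pairs if p.locality == "inter"])

    def compare(a: np.ndarray, b: np.ndarray, name: str) -> dict:
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"comparison {name!r} needs ≥ 2 pairs per group")
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        ks = stats.ks_2samp(a, b)
        return {
            "n_a": len(a),
            "n_b": len(b),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "ranksum_statistic": float(mw.statistic),
            "ranksum_p": float(mw.pvalue),
            "ks_statistic": float(ks.statistic),
            "ks_p": float(ks.pvalue),
        }

    edges = np.arange(0.0, 1.0 + bin_width, bin_width)

    def hist(values: np.ndarray) -> list[int]:
        return np.histogram(values, bins=edges)[0].tolist()

    out: dict = {"histogram_edges": edges.tolist(), "histograms": {
        "all": hist(all_ids),
        "species_specific": hist(specific),
        "intra": hist(intra),
        "inter": hist(inter),
    }}
    out["species_specific_vs_all"] = compare(specific, all_ids, "species_specific_vs_all")
    out["intra_vs_inter"] = compare(intra, inter, "intra_vs_inter")
    return out


def chromosome_distribution_test(summaries: Sequence[ChromosomeSummary],
                                 genome: ChromosomeSummary) -> dict:
    """Heterogeneity of duplicate content across chromosomes.

    Chi-square goodness of fit of per-chromosome duplicate-gene counts
    against an expectation proportional to gene counts (smallest cells
    merged when an expected count falls below 1), plus per-chromosome
    exact binomial tests of the intra count against the genome-wide intra
    fraction.
    """
    if len(summaries) < 2:
        return {"heterogeneity": None,
                "message": "single chromosome; heterogeneity test skipped",
                "per_chromosome_intra_binomial": {}}
    observed = np.array([s.n_dup_genes for s in summaries], dtype=float)
    gene_counts = np.array([s.n_genes for s in summaries], dtype=float)
    expected = observed.sum() * gene_counts / gene_counts.sum()
    # merge smallest cells until all expected counts are ≥ 1
    order = np.argsort(expected)
    obs_list, exp_list = observed[order].tolist(), expected[order].tolist()
    while len(exp_list) > 1 and exp_list[0] < 1.0:
        warnings.warn("expected count < 1; merging smallest cells", stacklevel=2)
        exp_list[1] += exp_list[0]
        obs_list[1] += obs_list[0]
        del exp_list[0], obs_list[0]
    chi2 = stats.chisquare(obs_list, f_exp=exp_list)
    genome_intra_fraction = (
        genome.n_dup_genes_intra / genome.n_dup_genes if genome.n_dup_genes else float("nan")
    )
    per_chrom = {}
    for s in summaries:
        n = s.n_dup_genes
        if n == 0 or math.isnan(genome_intra_fraction):
            continue
        test = stats.binomtest(s.n_dup_genes_intra, n, genome_intra_fraction,
                               alternative="two-sided")
        per_chrom[s.chromosome] = {
            "n_intra": s.n_dup_genes_intra,
            "n_dup_genes": n,
            "intra_fraction": s.n_dup_genes_intra / n,
            "p_value": float(test.pvalue),
            "excess_intra": s.n_dup_genes_intra / n > genome_intra_fraction,
        }
    return {
        "heterogeneity": {
            "statistic": float(chi2.statistic),
            "p_value": float(chi2.pvalue),
            "dof": len(exp_list) - 1,
        },
        "genome_intra_fraction": float(genome_intra_fraction),
        "per_chromosome_intra_binomial": per_chrom,
    }


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; the default analyses report raw p)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="fdr_bh")[1].tolist()
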