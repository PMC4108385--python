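"""On/off expression divergence and correlation-based expression similarity.

A gene is called *off* in a tissue when its FPKM is below 1 and *on* when
above 2; the 1–2 interval is an ambiguous zone that never counts toward
divergence.  A pair has diverged in a tissue when one gene is on and the
other off.  Profile similarity is the Pearson correlation r of
log2(FPKM + 1) across tissues, reported both raw and on the
variance-stabilized scale T(r) = ln((1 + r)/(1 − r)) (r clamped to
1 − 1e−6 in magnitude so the transform stays finite).  Only pairs in which
both genes are expressed in at least one tissue enter correlation-based
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "ExpressionComparison",
    "RegressionResult",
    "OFF_FPKM",
    "ON_FPKM",
    "log_transform",
    "call_state",
    "transform_r",
    "compare_pair_expression",
    "expression_table",
    "divergence_summary",
    "expression_vs_divergence_regression",
    "flag_high_divergence_pairs",
]

OFF_FPKM = 1.0
ON_FPKM = 2.0
_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class ExpressionComparison:
    """Expression divergence calls and profile similarity for one pair."""

    gene_a: str
    gene_b: str
    states_a: tuple[str, ...]
    states_b: tuple[str, ...]
    n_divergent_tissues: int
    r: float  # NaN when undefined (zero variance in either profile)
    transformed_r: float  # NaN when r undefined
    eligible: bool  # both genes on in ≥ 1 tissue
    n_tissues_expressed_a: int
    n_tissues_expressed_b: int


@dataclass(frozen=True)
class RegressionResult:
    """Binned OLS of transformed r on a divergence covariate."""

    covariate: str
    stratum: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n_pairs: int
    n_bins: int
    bin_mean_covariate: tuple[float, ...]
    bin_mean_transformed_r: tuple[float, ...]


def log_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(FPKM + offset); offset must be positive."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if (matrix.data.values < 0).any():
        raise ValueError("negative FPKM values")
    return np.log2(matrix.data + offset)


def call_state(fpkm: float) -> str:
    """off (< 1), on (> 2) or ambiguous (the 1–2 zone)."""
    if fpkm < OFF_FPKM:
        return "off"
    if fpkm > ON_FPKM:
        return "on"
    return "ambiguous"


def transform_r(r: float, eps: float = _CLAMP_EPS) -> float:
    """T(r) = ln((1 + r)/(1 − r)) with |r| clamped to 1 − eps."""
    if math.isnan(r):
        return float("nan")
    r = min(max(r, -1.0 + eps), 1.0 - eps)
    return math.log((1.0 + r) / (1.0 - r))


def compare_pair_expression(pair: tuple[str, str], matrix: ExpressionMatrix,
                            offset: float = 1.0, log_scale_r: bool = True) -> ExpressionComparison:
    """Per-tissue divergence calls and Pearson r for one duplicate pair.

    State calls are made on raw FPKM; r is computed across all tissues on
    log2(FPKM + offset) values (set ``log_scale_r=False`` for raw-scale r).
    r is undefined when either profile has zero variance.
    """
    a, b = pair
    fa = matrix.fpkm(a).to_numpy(float)
    fb = matrix.fpkm(b).to_numpy(float)
    states_a = tuple(call_state(v) for v in fa)
    states_b = tuple(call_state(v) for v in fb)
    n_div = sum(
        (sa == "on" and sb == "off") or (sa == "off" and sb == "on")
        for sa, sb in zip(states_a, states_b)
    )
    xa, xb = (np.log2(fa + offset), np.log2(fb + offset)) if log_scale_r else (fa, fb)
    if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:  # constant profile: r undefined
        r = float("nan")
    else:
        r = float(stats.pearsonr(xa, xb)[0])
    on_a = sum(s == "on" for s in states_a)
    on_b = sum(s == "on" for s in states_b)
    return ExpressionComparison(
        gene_a=a,
        gene_b=b,
        states_a=states_a,
        states_b=states_b,
        n_divergent_tissues=n_div,
        r=r,
        transformed_r=transform_r(r),
        eligible=on_a >= 1 and on_b >= 1,
        n_tissues_expressed_a=on_a,
        n_tissues_expressed_b=on_b,
    )


def expression_table(pairs: Sequence[tuple[str, str]], matrix: ExpressionMatrix,
                     offset: float = 1.0) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        cmp = compare_pair_expression((a, b), matrix, offset=offset)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "states_a": ",".join(cmp.states_a),
                "states_b": ",".join(cmp.states_b),
                "n_divergent_tissues": cmp.n_divergent_tissues,
                "r": cmp.r,
                "transformed_r": cmp.transformed_r,
                "eligible": cmp.eligible,
                "n_tissues_expressed_a": cmp.n_tissues_expressed_a,
                "n_tissues_expressed_b": cmp.n_tissues_expressed_b,
            }
        )
    return pd.DataFrame(rows).set_index(["gene_a", "gene_b"])


def divergence_summary(comparisons: Sequence[ExpressionComparison],
                       tissue_names: Sequence[str] | None = None,
                       lineage: Mapping[tuple[str, str], str] | None = None) -> dict:
    """Per-tissue divergent fractions and ≥1/≥2-tissue fractions.

    When a pair → lineage mapping is given, the same summaries are also
    reported restricted to species-specific pairs.
    """
    def summarize(group: Sequence[ExpressionComparison]) -> dict:
        n = len(group)
        if n == 0:
            return {"n_pairs": 0}
        n_tissues = len(group[0].states_a)
        per_tissue = []
        for i in range(n_tissues):
            frac = np.mean(
                [
                    (c.states_a[i] == "on" and c.states_b[i] == "off")
                    or (c.states_a[i] == "off" and c.states_b[i] == "on")
                    for c in group
                ]
            )
            per_tissue.append(float(frac))
        names = list(tissue_names) if tissue_names else [f"tissue{i+1}" for i in range(n_tissues)]
        return {
            "n_pairs": n,
            "per_tissue_divergent_fraction": dict(zip(names, per_tissue)),
            "fraction_divergent_ge1_tissue": float(
                np.mean([c.n_divergent_tissues >= 1 for c in group])
            ),
            "fraction_divergent_ge2_tissues": float(
                np.mean([c.n_divergent_tissues >= 2 for c in group])
            ),
        }

    out = {"all": summarize(comparisons)}
    if lineage is not None:
        specific = [
            c for c in comparisons
            if lineage.get((c.gene_a, c.gene_b)) == "species_specific"
        ]
        out["species_specific"] = summarize(specific)
    return out


def expression_vs_divergence_regression(
    comparisons: Sequence[ExpressionComparison],
    covariate_values: Sequence[float],
    covariate: str = "dS",
    dn_split: float | None = None,
    bin_size: int = 5,
) -> list[RegressionResult]:
    """Binned OLS of transformed r on dS or dN.

    Pairs are ranked by the covariate and grouped into consecutive bins of
    ``bin_size`` (trailing partial bin dropped, bin_size=1 is the unbinned
    regression); OLS is fit across bin means.  Only eligible pairs with a
    defined transformed r and a finite covariate enter.  For covariate
    "dN" with ``dn_split`` set, separate fits are returned below and above
    the split.
    """
    if len(comparisons) != len(covariate_values):
        raise ValueError("comparisons and covariate_values must be parallel")
    points = [
        (x, c.transformed_r)
        for c, x in zip(comparisons, covariate_values)
        if c.eligible and math.isfinite(c.transformed_r) and x is not None and math.isfinite(x)
    ]
    strata: list[tuple[str, list[tuple[float, float]]]] = []
    if covariate == "dN" and dn_split is not None:
        strata.append((f"dN<{dn_split}", [p for p in points if p[0] < dn_split]))
        strata.append((f"dN>={dn_split}", [p for p in points if p[0] >= dn_split]))
    else:
        strata.append(("all", points))

    results = []
    for name, pts in strata:
        n_bins = len(pts) // bin_size
        if n_bins < 3:
            raise ValueError(
                f"stratum {name!r}: need ≥ 3 bins of {bin_size}, have {len(pts)} pairs"
            )
        pts = sorted(pts, key=lambda p: p[0])
        xs, ys = [], []
        for b in range(n_bins):
            chunk = pts[b * bin_size : (b + 1) * bin_size]
            xs.append(float(np.mean([p[0] for p in chunk])))
            ys.append(float(np.mean([p[1] for p in chunk])))
        fit = stats.linregress(xs, ys)
        results.append(
            RegressionResult(
                covariate=covariate,
                stratum=name,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r=float(fit.rvalue),
                p_value=float(fit.pvalue),
                n_pairs=len(pts),
                n_bins=n_bins,
                bin_mean_covariate=tuple(xs),
                bin_mean_transformed_r=tuple(ys),
            )
        )
    return results


def flag_high_divergence_pairs(comparisons: Sequence[ExpressionComparison],
                               r_max: float,
                               lineage: Mapping[tuple[str, str], str]) -> list[tuple[str, str]]:
    """Species-specific eligible pairs with defined r below ``r_max``."""
    out = []
    for c in comparisons:
        if not c.eligible or math.isnan(c.r):
            continue
        if lineage.get((c.gene_a, c.gene_b)) != "species_specific":
            continue
        if c.r < r_max:
            out.append((c.gene_a, c.gene_b))
    return out
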