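"""Exon–intron structural divergence between duplicate genes.

Two genes differ in Class 1 when they have different numbers of coding
exons; in Class 2 when the exon counts are equal but at least one pair of
positionally homologous exons differs in length.  Exons are matched
positionally in transcription order (5′→3′, i.e. reversed genomic order on
the minus strand), which makes the classification symmetric in the two
genes and invariant to how either gene's strand is represented.

The trend of structural divergence against synonymous divergence is
summarized by ranking pairs on dS, grouping them into consecutive
fixed-size bins (default 200 pairs; a trailing partial bin is dropped) and
correlating the per-bin proportion of structurally divergent pairs with
the per-bin mean dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel

__all__ = [
    "StructureComparison",
    "BinnedTrend",
    "compare_structure",
    "structure_table",
    "structure_vs_ds_trend",
]


@dataclass(frozen=True)
class StructureComparison:
    """Structural class of one duplicate pair.

    ``differing_exon_indices`` are 1-based positions in transcription order
    where the two genes' exon lengths differ (Class 2 only).
    """

    gene_a: str
    gene_b: str
    n_exons_a: int
    n_exons_b: int
    structure_class: str  # "identical" | "class1" | "class2"
    differing_exon_indices: tuple[int, ...] = ()

    @property
    def divergent(self) -> bool:
        return self.structure_class != "identical"


@dataclass(frozen=True)
class BinnedTrend:
    """Rank-binned trend of a per-pair quantity against a covariate."""

    bin_size: int
    mean_covariate: tuple[float, ...]
    bin_value: tuple[float, ...]  # proportion divergent, or mean transformed r
    r: float
    p_value: float

    @property
    def n_bins(self) -> int:
        return len(self.mean_covariate)


def compare_structure(model_a: GeneModel, model_b: GeneModel,
                      use_full_exons: bool = False) -> StructureComparison:
    """Classify the exon-structure difference between two gene models.

    ``use_full_exons`` is accepted for signature stability; the models carry
    coding exons, which is the default comparison basis.
    """
    lens_a = model_a.exon_lengths_5to3
    lens_b = model_b.exon_lengths_5to3
    if len(lens_a) != len(lens_b):
        cls, diff = "class1", ()
    else:
        diff = tuple(i + 1 for i, (la, lb) in enumerate(zip(lens_a, lens_b)) if la != lb)
        cls = "class2" if diff else "identical"
    return StructureComparison(
        gene_a=model_a.gene_id,
        gene_b=model_b.gene_id,
        n_exons_a=len(lens_a),
        n_exons_b=len(lens_b),
        structure_class=cls,
        differing_exon_indices=diff,
    )


def structure_table(pairs: Sequence[tuple[str, str]],
                    gene_models: Mapping[str, GeneModel]) -> pd.DataFrame:
    """Per-pair structural classification as a DataFrame."""
    rows = []
    for a, b in pairs:
        cmp = compare_structure(gene_models[a], gene_models[b])
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "n_exons_a": cmp.n_exons_a,
                "n_exons_b": cmp.n_exons_b,
                "structure_class": cmp.structure_class,
                "differing_exon_indices": ",".join(map(str, cmp.differing_exon_indices)),
            }
        )
    return pd.DataFrame(rows).set_index(["gene_a", "gene_b"])


def structure_vs_ds_trend(comparisons: Sequence[StructureComparison],
                          ds_values: Sequence[float],
                          bin_size: int = 200) -> BinnedTrend:
    """Binned proportion of structurally divergent pairs against dS.

    ``comparisons`` and ``ds_values`` are parallel; pairs with NaN
    (saturated) dS are excluded.  Requires at least 2 full bins.  When every
    bin has the same proportion the correlation is undefined and reported
    as NaN with p = NaN.
    """
    if len(comparisons) != len(ds_values):
        raise ValueError("comparisons and ds_values must be parallel")
    usable = [(ds, cmp.divergent) for cmp, ds in zip(comparisons, ds_values)
              if ds is not None and math.isfinite(ds)]
    n_bins = len(usable) // bin_size
    if n_bins < 2:
        raise ValueError(
            f"need at least 2 full bins of {bin_size}; only {len(usable)} usable pairs"
        )
    usable.sort(key=lambda x: x[0])
    mean_ds, props = [], []
    for b in range(n_bins):
        chunk = usable[b * bin_size : (b + 1) * bin_size]
        mean_ds.append(float(np.mean([c[0] for c in chunk])))
        props.append(float(np.mean([c[1] for c in chunk])))
    if np.std(props) == 0.0 or np.std(mean_ds) == 0.0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(mean_ds, props)
    return BinnedTrend(
        bin_size=bin_size,
        mean_covariate=tuple(mean_ds),
        bin_value=tuple(props),
        r=float(r),
        p_value=float(p),
    )
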