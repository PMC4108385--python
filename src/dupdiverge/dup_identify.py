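"""Duplicate gene pair identification from all-vs-all protein hits.

A duplicate pair is a reciprocal best hit (RBH) that passes two criteria:
(1) the aligned region covers ≥ 80% of the longer protein, and (2) the
identity exceeds a length-dependent homology threshold — 30% for aligned
regions longer than 150 aa, and for shorter regions the classic
length-scaled curve I_min(L) = 0.01·n + 4.8·L^(−0.32·(1 + e^(−L/1000)))
with n = 6.  Both the constant and the curve parameters are
config-overridable.

Pairs touching a pseudogene are discarded; surviving pairs are classified
as intra- vs interchromosomal and as species-specific (both genes lack any
homolog outside the focal species) vs shared, and summarized per
chromosome as gene counts and duplicate content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AlignmentHit, GeneModel, SequenceRecord

__all__ = [
    "DuplicateCriteria",
    "DuplicatePair",
    "ChromosomeSummary",
    "reciprocal_best_hits",
    "apply_duplicate_criteria",
    "filter_pseudogenes",
    "classify_pairs",
    "summarize_by_chromosome",
    "identify_duplicates",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class DuplicateCriteria:
    """Coverage and identity thresholds for calling a pair a duplicate."""

    min_coverage: float = 0.8
    long_identity: float = 0.30
    long_length: int = 150
    curve_n: float = 6.0
    curve_scale: float = 4.8
    curve_exponent: float = -0.32

    def min_identity(self, aligned_length: int) -> float:
        """Length-dependent identity threshold (fraction in [0, 1])."""
        L = aligned_length
        if L > self.long_length:
            return self.long_identity
        return 0.01 * self.curve_n + self.curve_scale * L ** (
            self.curve_exponent * (1.0 + math.exp(-L / 1000.0))
        )


@dataclass(frozen=True)
class DuplicatePair:
    """One duplicate gene pair in canonical (lexicographic) order."""

    gene_a: str
    gene_b: str
    identity: float
    aligned_length: int
    coverage: float = float("nan")
    locality: str = ""  # "intra" | "inter"
    lineage: str = ""  # "species_specific" | "shared"

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError(f"pair not in canonical order: {self.gene_a!r} ≥ {self.gene_b!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    n_genes: int
    n_dup_genes_intra: int
    n_dup_genes_inter: int
    n_specific_intra: int
    n_specific_inter: int

    @property
    def n_dup_genes(self) -> int:
        return self.n_dup_genes_intra + self.n_dup_genes_inter

    @property
    def n_specific(self) -> int:
        return self.n_specific_intra + self.n_specific_inter

    @property
    def duplicate_content(self) -> float:
        """Percent of the chromosome's genes that participate in a duplicate pair."""
        return 100.0 * self.n_dup_genes / self.n_genes if self.n_genes else 0.0

    @property
    def specific_content(self) -> float:
        return 100.0 * self.n_specific / self.n_genes if self.n_genes else 0.0


def reciprocal_best_hits(hits: Sequence[AlignmentHit]) -> list[DuplicatePair]:
    """Reciprocal best hits with deterministic tie-breaking.

    For each ordered pair only the top-scoring HSP is considered; per query
    the best subject is chosen by bit score, then identity, then
    lexicographic subject id.  A pair survives iff each member is the
    other's best subject.
    """
    # top HSP per ordered (query, subject)
    best_hsp: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best_hsp.get(key)
        if cur is None or (h.bit_score, h.percent_identity) > (cur.bit_score, cur.percent_identity):
            best_hsp[key] = h
    # best subject per query: bit score, then identity, then smaller subject id
    def beats(new: AlignmentHit, cur: AlignmentHit) -> bool:
        if new.bit_score != cur.bit_score:
            return new.bit_score > cur.bit_score
        if new.percent_identity != cur.percent_identity:
            return new.percent_identity > cur.percent_identity
        return new.subject_id < cur.subject_id

    best_subject: dict[str, AlignmentHit] = {}
    for (q, s), h in best_hsp.items():
        cur = best_subject.get(q)
        if cur is None or beats(h, cur):
            best_subject[q] = h

    pairs: list[DuplicatePair] = []
    for q, h in best_subject.items():
        s = h.subject_id
        if q >= s:
            continue  # emit each unordered pair once, from its smaller member
        partner = best_subject.get(s)
        if partner is None or partner.subject_id != q:
            continue
        back = best_hsp[(s, q)]
        identity = (h.percent_identity + back.percent_identity) / 2.0
        length = max(h.aligned_length, back.aligned_length)
        pairs.append(DuplicatePair(gene_a=q, gene_b=s, identity=identity, aligned_length=length))
    return sorted(pairs, key=lambda p: p.key)


def apply_duplicate_criteria(candidates: Sequence[DuplicatePair],
                             proteins: Mapping[str, SequenceRecord],
                             criteria: DuplicateCriteria | None = None) -> list[DuplicatePair]:
    """Keep candidates passing the coverage and identity criteria."""
    criteria = criteria or DuplicateCriteria()
    kept = []
    for pair in candidates:
        for g in pair.key:
            if g not in proteins:
                raise KeyError(f"protein {g!r} missing from FASTA")
        len_a = len(proteins[pair.gene_a].residues.rstrip("*"))
        len_b = len(proteins[pair.gene_b].residues.rstrip("*"))
        coverage = pair.aligned_length / max(len_a, len_b)
        if coverage < criteria.min_coverage:
            continue
        if pair.identity < criteria.min_identity(pair.aligned_length):
            continue
        kept.append(replace(pair, coverage=min(coverage, 1.0)))
    return kept


def filter_pseudogenes(pairs: Sequence[DuplicatePair],
                       gene_models: Mapping[str, GeneModel] | Sequence[GeneModel]) -> list[DuplicatePair]:
    """Drop every pair with at least one pseudogene member."""
    models = _as_mapping(gene_models)
    kept = []
    for pair in pairs:
        for g in pair.key:
            if g not in models:
                raise KeyError(f"gene {g!r} missing from gene models")
        if models[pair.gene_a].is_pseudogene or models[pair.gene_b].is_pseudogene:
            continue
        kept.append(pair)
    return kept


def classify_pairs(pairs: Sequence[DuplicatePair],
                   gene_models: Mapping[str, GeneModel] | Sequence[GeneModel]) -> list[DuplicatePair]:
    """Set locality (intra/inter-chromosomal) and lineage class on each pair.

    A pair is species-specific only when BOTH genes lack a recorded homolog
    outside the focal species.
    """
    models = _as_mapping(gene_models)
    out = []
    for pair in pairs:
        ma, mb = models[pair.gene_a], models[pair.gene_b]
        locality = "intra" if ma.chromosome == mb.chromosome else "inter"
        lineage = (
            "species_specific" if ma.lineage_specific and mb.lineage_specific else "shared"
        )
        out.append(replace(pair, locality=locality, lineage=lineage))
    return out


def summarize_by_chromosome(pairs: Sequence[DuplicatePair],
                            gene_models: Mapping[str, GeneModel] | Sequence[GeneModel],
                            enrichment_fold: float = 2.0
                            ) -> tuple[list[ChromosomeSummary], ChromosomeSummary, pd.DataFrame]:
    """Per-chromosome duplicate-gene counts, contents and fold enrichment.

    A gene is counted once per chromosome and locality class if it
    participates in ≥ 1 pair of that class (a gene duplicated both intra-
    and interchromosomally is counted in both columns).  Returns the
    per-chromosome summaries, a genome-total row, and a DataFrame with
    fold enrichment vs the genome average plus a flag for chromosomes
    exceeding ``enrichment_fold`` times the genome duplicate content.
    """
    models = _as_mapping(gene_models)
    intra_genes: dict[str, set[str]] = {}
    inter_genes: dict[str, set[str]] = {}
    spec_intra: dict[str, set[str]] = {}
    spec_inter: dict[str, set[str]] = {}
    for pair in pairs:
        locality = pair.locality or (
            "intra" if models[pair.gene_a].chromosome == models[pair.gene_b].chromosome else "inter"
        )
        target, spec_target = (
            (intra_genes, spec_intra) if locality == "intra" else (inter_genes, spec_inter)
        )
        for g in pair.key:
            chrom = models[g].chromosome
            target.setdefault(chrom, set()).add(g)
            if pair.lineage == "species_specific":
                spec_target.setdefault(chrom, set()).add(g)

    genes_per_chrom: dict[str, int] = {}
    for m in models.values():
        genes_per_chrom[m.chromosome] = genes_per_chrom.get(m.chromosome, 0) + 1

    summaries = []
    for chrom in sorted(genes_per_chrom, key=_chrom_sort_key):
        summaries.append(
            ChromosomeSummary(
                chromosome=chrom,
                n_genes=genes_per_chrom[chrom],
                n_dup_genes_intra=len(intra_genes.get(chrom, ())),
                n_dup_genes_inter=len(inter_genes.get(chrom, ())),
                n_specific_intra=len(spec_intra.get(chrom, ())),
                n_specific_inter=len(spec_inter.get(chrom, ())),
            )
        )
    genome = ChromosomeSummary(
        chromosome="All",
        n_genes=sum(s.n_genes for s in summaries),
        n_dup_genes_intra=sum(s.n_dup_genes_intra for s in summaries),
        n_dup_genes_inter=sum(s.n_dup_genes_inter for s in summaries),
        n_specific_intra=sum(s.n_specific_intra for s in summaries),
        n_specific_inter=sum(s.n_specific_inter for s in summaries),
    )
    rows = []
    for s in summaries:
        fold = (s.duplicate_content / genome.duplicate_content) if genome.duplicate_content else float("nan")
        rows.append(
            {
                "chromosome": s.chromosome,
                "n_genes": s.n_genes,
                "n_dup_genes_intra": s.n_dup_genes_intra,
                "n_dup_genes_inter": s.n_dup_genes_inter,
                "n_dup_genes": s.n_dup_genes,
                "duplicate_content_pct": s.duplicate_content,
                "n_specific_intra": s.n_specific_intra,
                "n_specific_inter": s.n_specific_inter,
                "n_specific": s.n_specific,
                "specific_content_pct": s.specific_content,
                "fold_enrichment": fold,
                "enriched": bool(fold > enrichment_fold),
            }
        )
    table = pd.DataFrame(rows)
    return summaries, genome, table


def identify_duplicates(hits: Sequence[AlignmentHit],
                        proteins: Mapping[str, SequenceRecord],
                        gene_models: Mapping[str, GeneModel] | Sequence[GeneModel],
                        criteria: DuplicateCriteria | None = None) -> list[DuplicatePair]:
    """RBH → criteria → pseudogene filter → classification, in one call."""
    candidates = reciprocal_best_hits(hits)
    pairs = apply_duplicate_criteria(candidates, proteins, criteria)
    pairs = filter_pseudogenes(pairs, gene_models)
    return classify_pairs(pairs, gene_models)


def pairs_to_frame(pairs: Sequence[DuplicatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "identity": p.identity,
                "aligned_length": p.aligned_length,
                "coverage": p.coverage,
                "locality": p.locality,
                "lineage": p.lineage,
            }
            for p in pairs
        ]
    )


def _as_mapping(gene_models) -> Mapping[str, GeneModel]:
    if isinstance(gene_models, Mapping):
        return gene_models
    return {m.gene_id: m for m in gene_models}


def _chrom_sort_key(chrom: str):
    tail = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(tail)) if tail.isdigit() else (1, tail)
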