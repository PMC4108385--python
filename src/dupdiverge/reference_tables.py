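"""Published bovine-genome duplicate-gene summary counts, as fixture inputs.

These are the per-chromosome counts of a genome-wide duplicate-gene survey
of the bovine genome (Ensembl release 67 annotation): genes per chromosome,
genes participating in intra- and interchromosomal duplicate pairs, and the
same restricted to cattle-specific pairs; plus the genome-wide structural
class counts (different exon number = Class 1; same number but differing
exon lengths = Class 2).

The builders reconstruct a concrete gene-model/pair configuration realizing
those gene counts so the summarization and classification operations can be
exercised against the published percentages.  Where a published gene count
is odd (a gene participating in more than one surviving pair), a three-gene
chain of two pairs is used; chromosome summaries count genes, not pairs, so
the counts are preserved.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .dup_identify import DuplicatePair, classify_pairs
from .io_formats import GeneModel

__all__ = [
    "chromosome_counts",
    "published_contents",
    "structure_class_counts",
    "build_genome_fixture",
    "build_structure_fixture",
]

# chromosome, genes, intra dup genes, inter dup genes,
# cattle-specific intra dup genes, cattle-specific inter dup genes
# (cattle-specific intra totals 994 genes and inter 430 = 215 pairs,
#  i.e. 497 + 215 = 712 cattle-specific pairs)
_CHROMOSOME_COUNTS = [
    ("1", 985, 52, 175, 14, 24),
    ("2", 1021, 34, 201, 16, 18),
    ("3", 1372, 124, 258, 66, 23),
    ("4", 855, 78, 146, 42, 14),
    ("5", 1323, 122, 256, 78, 28),
    ("6", 692, 28, 128, 8, 8),
    ("7", 1396, 144, 252, 64, 16),
    ("8", 829, 48, 135, 28, 6),
    ("9", 602, 28, 107, 10, 18),
    ("10", 1074, 114, 189, 72, 19),
    ("11", 1047, 54, 205, 12, 13),
    ("12", 414, 12, 90, 4, 6),
    ("13", 850, 40, 178, 22, 18),
    ("14", 571, 14, 115, 4, 16),
    ("15", 1050, 220, 139, 144, 27),
    ("16", 710, 36, 129, 12, 15),
    ("17", 665, 44, 119, 14, 17),
    ("18", 1236, 138, 167, 60, 12),
    ("19", 1347, 102, 230, 40, 15),
    ("20", 384, 14, 69, 2, 8),
    ("21", 731, 22, 118, 18, 13),
    ("22", 608, 14, 127, 2, 11),
    ("23", 785, 100, 94, 56, 13),
    ("24", 347, 18, 59, 6, 4),
    ("25", 766, 50, 116, 14, 5),
    ("26", 437, 26, 81, 6, 13),
    ("27", 274, 16, 56, 10, 6),
    ("28", 355, 10, 61, 6, 5),
    ("29", 705, 94, 111, 64, 14),
    ("X", 1128, 156, 199, 100, 25),
]

# published duplicate-content percentages (one decimal place)
_PUBLISHED_CONTENT = {
    "1": (23.0, 3.9), "2": (23.0, 3.3), "3": (27.8, 6.5), "4": (26.2, 6.5),
    "5": (28.6, 8.0), "6": (22.5, 2.3), "7": (28.4, 5.7), "8": (22.1, 4.1),
    "9": (22.4, 4.7), "10": (28.2, 8.5), "11": (24.7, 2.4), "12": (24.6, 2.4),
    "13": (25.6, 4.7), "14": (22.6, 3.5), "15": (34.2, 16.3), "16": (23.2, 3.8),
    "17": (24.5, 4.7), "18": (24.7, 5.8), "19": (24.6, 4.1), "20": (21.6, 2.6),
    "21": (19.2, 4.2), "22": (23.2, 2.1), "23": (24.7, 8.8), "24": (22.2, 2.9),
    "25": (21.7, 2.5), "26": (24.5, 4.3), "27": (26.3, 5.8), "28": (20.0, 3.1),
    "29": (29.1, 11.1), "X": (31.5, 11.1), "All": (25.5, 5.8),
}

# total pairs, class 1 pairs, class 2 pairs; all pairs then cattle-specific
_STRUCTURE_COUNTS = {
    "all": {"total": 3131, "class1": 1827, "class2": 1198},
    "species_specific": {"total": 712, "class1": 383, "class2": 242},
}


def chromosome_counts() -> pd.DataFrame:
    """Published per-chromosome counts as a DataFrame."""
    return pd.DataFrame(
        _CHROMOSOME_COUNTS,
        columns=[
            "chromosome", "n_genes", "intra_dup_genes", "inter_dup_genes",
            "specific_intra_dup_genes", "specific_inter_dup_genes",
        ],
    )


def published_contents() -> dict[str, tuple[float, float]]:
    """chromosome → (duplicate content %, species-specific content %)."""
    return dict(_PUBLISHED_CONTENT)


def structure_class_counts() -> dict[str, dict[str, int]]:
    """Published structural-class pair counts, overall and species-specific."""
    return {k: dict(v) for k, v in _STRUCTURE_COUNTS.items()}


def _single_exon_model(gene_id: str, chrom: str, specific: bool) -> GeneModel:
    return GeneModel(
        gene_id=gene_id, chromosome=chrom, strand="+",
        coding_exons=((101, 400),), lineage_specific=specific,
    )


def _pair(a: str, b: str) -> DuplicatePair:
    a, b = sorted((a, b))
    return DuplicatePair(gene_a=a, gene_b=b, identity=0.9, aligned_length=200)


def _group_pairs(gene_ids: list[str]) -> list[tuple[str, str]]:
    """Disjoint pairs, using a 3-gene chain when the count is odd."""
    pairs = []
    ids = list(gene_ids)
    if len(ids) % 2 == 1:
        g0, g1, g2 = ids[:3]
        pairs += [(g0, g1), (g1, g2)]
        ids = ids[3:]
    for i in range(0, len(ids), 2):
        pairs.append((ids[i], ids[i + 1]))
    return pairs


def build_genome_fixture() -> tuple[list[GeneModel], list[DuplicatePair]]:
    """Gene models and classified pairs realizing the published counts."""
    models: list[GeneModel] = []
    pairs: list[tuple[str, str]] = []
    counter = 0

    def new_gene(chrom: str, specific: bool) -> str:
        nonlocal counter
        gid = f"G{counter:06d}"
        counter += 1
        models.append(_single_exon_model(gid, chrom, specific))
        return gid

    inter_slots_cs: list[str] = []
    inter_slots_other: list[str] = []
    used_per_chrom: dict[str, int] = {}
    for chrom, n_genes, intra, inter, cs_intra, cs_inter in _CHROMOSOME_COUNTS:
        cs_genes = [new_gene(chrom, True) for _ in range(cs_intra)]
        other_genes = [new_gene(chrom, False) for _ in range(intra - cs_intra)]
        pairs += _group_pairs(cs_genes)
        pairs += _group_pairs(other_genes)
        inter_slots_cs += [new_gene(chrom, True) for _ in range(cs_inter)]
        inter_slots_other += [new_gene(chrom, False) for _ in range(inter - cs_inter)]
        used_per_chrom[chrom] = intra + inter

    # interchromosomal matching: chromosome-sorted slots, i with i + half;
    # no chromosome holds more than half the slots, so partners always differ
    for slots in (inter_slots_cs, inter_slots_other):
        half = len(slots) // 2
        pairs += [(slots[i], slots[i + half]) for i in range(half)]

    by_id = {m.gene_id: m for m in models}
    for chrom, n_genes, *_ in _CHROMOSOME_COUNTS:
        for _ in range(n_genes - used_per_chrom[chrom]):
            new_gene(chrom, False)

    dup_pairs = [_pair(a, b) for a, b in pairs]
    all_models = {m.gene_id: m for m in models}
    return models, classify_pairs(dup_pairs, all_models)


def build_structure_fixture() -> tuple[list[tuple[str, str]], dict[str, GeneModel], dict[tuple[str, str], str]]:
    """Gene-model pairs realizing the published structural-class counts.

    Returns (pair keys, gene models, pair → lineage map).  Class 1 pairs get
    differing exon counts, Class 2 pairs equal counts with one differing
    exon length, remaining pairs identical layouts.
    """
    models: dict[str, GeneModel] = {}
    keys: list[tuple[str, str]] = []
    lineage: dict[tuple[str, str], str] = {}
    counter = 0

    def make_pair(kind: str, specific: bool) -> None:
        nonlocal counter
        a, b = f"S{counter:06d}", f"S{counter + 1:06d}"
        counter += 2
        exons_a = ((101, 250), (451, 600))
        if kind == "class1":
            exons_b = ((101, 250), (451, 600), (801, 900))
        elif kind == "class2":
            exons_b = ((101, 250), (451, 588))
        else:
            exons_b = exons_a
        models[a] = GeneModel(gene_id=a, chromosome="1", strand="+",
                              coding_exons=exons_a, lineage_specific=specific)
        models[b] = GeneModel(gene_id=b, chromosome="1", strand="+",
                              coding_exons=exons_b, lineage_specific=specific)
        keys.append((a, b))
        lineage[(a, b)] = "species_specific" if specific else "shared"

    for group, specific in (("species_specific", True), ("all", False)):
        counts = _STRUCTURE_COUNTS[group]
        if group == "all":
            # the published totals include the species-specific pairs
            counts = {
                k: counts[k] - _STRUCTURE_COUNTS["species_specific"][k]
                for k in counts
            }
        n_identical = counts["total"] - counts["class1"] - counts["class2"]
        for _ in range(counts["class1"]):
            make_pair("class1", specific)
        for _ in range(counts["class2"]):
            make_pair("class2", specific)
        for _ in range(n_identical):
            make_pair("identical", specific)
    return keys, models, lineage
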