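"""Synthetic gene families with controllable sequence, structure and
expression divergence.

The generator produces everything the pipeline consumes — CDS/protein FASTA,
gene-model TSV, an alignment hit table, a lineage table and a tissue
expression matrix — together with a truth table, so every downstream stage
can be tested end-to-end without external data.

Generative model, per duplicate pair with divergence-time scale ``t``
(expected proposed nucleotide changes per codon, summed over both copies):

* **Sequence** — an ancestral CDS of uniform sense codons is duplicated and
  each copy accumulates Poisson(L·t/2) proposed point mutations; a proposal
  is accepted with probability 1 if synonymous and ω if nonsynonymous, and
  rejected outright if it would create a stop codon (a minimal
  Goldman–Yang-flavoured scheme with equal nucleotide exchange rates).
* **Structure** — Poisson(rate·t) exon-structure events, each an exon gain,
  an exon loss, or a reading-frame-preserving boundary shift (±3k nt),
  applied to a random copy.
* **Expression** — per-tissue log2 expression drawn bivariate-normal with
  correlation ρ = e^(−λt), exponentiated to FPKM; tissue silencing events
  (FPKM forced below 1 in one copy) occur with a logistic-in-t probability.

All randomness flows through a single :class:`numpy.random.Generator`
(PCG64), so a fixed seed gives byte-identical bundles across platforms.
The exact draw order of :func:`simulate_cds_pair` is part of its contract
(documented in the docstring) so that replay oracles can verify realized
substitution counts independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    SequenceRecord,
    write_alignment_table,
    write_fasta,
    write_gene_models_tsv,
    write_lineage_table,
)
from .seq_divergence import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    align_proteins_global,
    alignment_to_hit,
    codon_site_counts,
)

__all__ = [
    "SimulationConfig",
    "CdsPairSim",
    "StructurePairSim",
    "simulate_cds_pair",
    "simulate_structure_pair",
    "simulate_expression_pair",
    "simulate_study",
    "StudyBundle",
]

_NT = "ACGT"


@dataclass
class SimulationConfig:
    """Parameters of a simulated duplicate-gene study.

    Defaults emulate the regimes of the bovine study: 7 tissues, roughly a
    third of pairs intrachromosomal, divergence times spanning near-identity
    to near-saturation, a structure-event rate that leaves ~90% of pairs
    structurally divergent, and an expression correlation decaying with time.
    """

    seed: int = 0
    n_pairs: int = 200
    n_chromosomes: int = 30
    intra_fraction: float = 0.31
    branch_length_range: tuple[float, float] = (0.02, 1.0)
    omega_range: tuple[float, float] = (0.05, 0.5)
    structure_event_rate: float = 8.0
    expression_decay: float = 1.0
    tissue_count: int = 7
    species_specific_t_max: float = 0.25
    length_codons_range: tuple[int, int] = (100, 200)
    base_exons_range: tuple[int, int] = (2, 10)
    silencing_max: float = 0.4
    silencing_midpoint: float = 0.3
    silencing_width: float = 0.15
    sd_extra_decay: float = 0.0
    alignment_scope: str = "within_pairs"  # or "all_vs_all"
    tissue_names: tuple[str, ...] = (
        "adipose", "muscle", "hypothalamus", "duodenum", "liver", "lung", "kidney",
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.intra_fraction <= 1.0:
            raise ValueError("intra_fraction must be in [0, 1]")
        for lo, hi, name in (
            (*self.branch_length_range, "branch_length_range"),
            (*self.omega_range, "omega_range"),
        ):
            if lo < 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 ≤ min ≤ max")
        for rate, name in (
            (self.structure_event_rate, "structure_event_rate"),
            (self.expression_decay, "expression_decay"),
            (self.sd_extra_decay, "sd_extra_decay"),
        ):
            if rate < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.tissue_count < 2:
            raise ValueError("tissue_count must be ≥ 2")
        if self.alignment_scope not in {"within_pairs", "all_vs_all"}:
            raise ValueError("alignment_scope must be 'within_pairs' or 'all_vs_all'")
        if len(self.tissue_names) < self.tissue_count:
            self.tissue_names = tuple(
                f"tissue{i + 1}" for i in range(self.tissue_count)
            )
        else:
            self.tissue_names = tuple(self.tissue_names[: self.tissue_count])


@dataclass(frozen=True)
class CdsPairSim:
    """A simulated duplicate CDS pair with realized substitution truth."""

    cds_a: str
    cds_b: str
    true_dS: float  # accepted synonymous events per ancestral synonymous site
    true_dN: float
    ancestral: str
    syn_events: int
    nonsyn_events: int


def translate_cds(cds: str) -> str:
    """Translate an in-frame, stop-free CDS to protein."""
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def simulate_cds_pair(ancestral_length_codons: int, t: float, omega: float,
                      rng: np.random.Generator) -> CdsPairSim:
    """Duplicate a random ancestral CDS and diverge both copies.

    Draw order (the replay contract):

    1. ancestor — one ``rng.integers(0, 61)`` per codon, indexing the sorted
       sense-codon list;
    2. copy A then copy B — ``n = rng.poisson(L · t / 2)`` events, each
       drawing ``site = rng.integers(0, 3L)``, ``alt = rng.integers(0, 3)``
       (indexing "ACGT" with the current nucleotide removed); a stop-creating
       candidate is rejected with no further draw, a synonymous candidate is
       accepted, and a nonsynonymous candidate draws ``u = rng.random()`` and
       is accepted iff ``u < ω``.

    ``true_dS``/``true_dN`` are the accepted synonymous/nonsynonymous event
    counts (both copies) divided by the NG86 synonymous/nonsynonymous site
    counts of the ancestor.
    """
    if ancestral_length_codons < 50:
        raise ValueError("ancestral length must be ≥ 50 codons")
    if t < 0:
        raise ValueError("t must be ≥ 0")
    if 0.75 * omega * t > np.log(5.0):
        warnings.warn(
            "t so large that expected protein identity < 20%; pairs may fall "
            "below the duplicate-detection threshold",
            stacklevel=2,
        )
    L = ancestral_length_codons
    ancestor = "".join(SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))] for _ in range(L))

    def evolve(seq: str) -> tuple[str, int, int]:
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        syn = non = 0
        n_events = rng.poisson(L * t / 2.0)
        for _ in range(n_events):
            site = int(rng.integers(0, 3 * L))
            ci, pos = divmod(site, 3)
            current = codons[ci]
            alts = [nt for nt in _NT if nt != current[pos]]
            cand_nt = alts[int(rng.integers(0, 3))]
            candidate = current[:pos] + cand_nt + current[pos + 1 :]
            if candidate in STOP_CODONS:
                continue
            if GENETIC_CODE[candidate] == GENETIC_CODE[current]:
                codons[ci] = candidate
                syn += 1
            else:
                if rng.random() < omega:
                    codons[ci] = candidate
                    non += 1
        return "".join(codons), syn, non

    cds_a, syn_a, non_a = evolve(ancestor)
    cds_b, syn_b, non_b = evolve(ancestor)
    S_anc = sum(codon_site_counts(ancestor[i : i + 3])[0] for i in range(0, 3 * L, 3))
    N_anc = 3.0 * L - S_anc
    syn_events = syn_a + syn_b
    nonsyn_events = non_a + non_b
    return CdsPairSim(
        cds_a=cds_a,
        cds_b=cds_b,
        true_dS=syn_events / S_anc if S_anc else 0.0,
        true_dN=nonsyn_events / N_anc if N_anc else 0.0,
        ancestral=ancestor,
        syn_events=syn_events,
        nonsyn_events=nonsyn_events,
    )


@dataclass(frozen=True)
class StructureEvent:
    kind: str  # "gain" | "loss" | "shift"
    copy: int  # 0 = a, 1 = b
    exon_index: int
    delta_nt: int  # signed length change of the affected exon (shift/gain/loss)


@dataclass(frozen=True)
class StructurePairSim:
    model_a: GeneModel
    model_b: GeneModel
    events: tuple[StructureEvent, ...]

    @property
    def net_exon_change(self) -> int:
        return self.model_a.n_exons - self.model_b.n_exons


def _materialize_model(gene_id: str, chromosome: str, strand: str,
                       exon_lengths: Sequence[int], start: int = 1001,
                       intron: int = 200, **kw) -> GeneModel:
    exons = []
    pos = start
    for length in exon_lengths:
        exons.append((pos, pos + length - 1))
        pos += length + intron
    return GeneModel(gene_id=gene_id, chromosome=chromosome, strand=strand,
                     coding_exons=tuple(exons), **kw)


def simulate_structure_pair(base_exons: int, t: float, rate: float,
                            rng: np.random.Generator,
                            base_lengths: Sequence[int] | None = None,
                            gene_ids: tuple[str, str] = ("simA", "simB"),
                            chromosomes: tuple[str, str] = ("chrU", "chrU"),
                            strands: tuple[str, str] = ("+", "+"),
                            lineage_specific: bool = False) -> StructurePairSim:
    """Duplicate an exon layout and apply Poisson(rate·t) structure events.

    Events are exon gain, exon loss (only when the copy still has >1 exon)
    or a frame-preserving boundary shift of ±3k nucleotides, each applied to
    a randomly chosen copy.  Exon lengths are kept multiples of 3 and ≥ 3 nt.
    """
    if base_exons < 1:
        raise ValueError("base_exons must be ≥ 1")
    if base_lengths is None:
        base_lengths = [3 * int(rng.integers(20, 80)) for _ in range(base_exons)]
    else:
        base_lengths = list(base_lengths)
        if len(base_lengths) != base_exons:
            raise ValueError("base_lengths must have base_exons entries")
    layouts = [list(base_lengths), list(base_lengths)]
    events: list[StructureEvent] = []
    n_events = int(rng.poisson(rate * t))
    for _ in range(n_events):
        copy = int(rng.integers(0, 2))
        layout = layouts[copy]
        kinds = ["gain", "shift"] + (["loss"] if len(layout) > 1 else [])
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind == "gain":
            idx = int(rng.integers(0, len(layout) + 1))
            length = 3 * int(rng.integers(10, 60))
            layout.insert(idx, length)
            events.append(StructureEvent("gain", copy, idx, length))
        elif kind == "loss":
            idx = int(rng.integers(0, len(layout)))
            removed = layout.pop(idx)
            events.append(StructureEvent("loss", copy, idx, -removed))
        else:
            idx = int(rng.integers(0, len(layout)))
            k = int(rng.integers(1, 11))
            sign = 1 if rng.random() < 0.5 else -1
            delta = 3 * k * sign
            if layout[idx] + delta < 3:
                delta = 3 * k
            layout[idx] += delta
            events.append(StructureEvent("shift", copy, idx, delta))
    model_a = _materialize_model(gene_ids[0], chromosomes[0], strands[0], layouts[0],
                                 lineage_specific=lineage_specific)
    model_b = _materialize_model(gene_ids[1], chromosomes[1], strands[1], layouts[1],
                                 lineage_specific=lineage_specific)
    return StructurePairSim(model_a=model_a, model_b=model_b, events=tuple(events))


def silencing_probability(t: float, p_max: float = 0.4, midpoint: float = 0.3,
                          width: float = 0.15) -> float:
    """Logistic-in-t probability that a tissue is silenced in one copy."""
    return p_max / (1.0 + np.exp(-(t - midpoint) / width))


def simulate_expression_pair(t: float, lam: float, n_tissues: int,
                             rng: np.random.Generator,
                             log2_mean: float = 3.0, log2_sd: float = 2.0,
                             silencing_max: float = 0.4,
                             silencing_midpoint: float = 0.3,
                             silencing_width: float = 0.15,
                             extra_decay: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """FPKM profiles of a duplicate pair across tissues.

    Per tissue, (log2 a, log2 b) is bivariate normal with correlation
    ρ = e^(−λt − extra_decay); silencing then forces one copy's FPKM below 1
    with probability ``silencing_probability(t)``.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be ≥ 2")
    rho = float(np.exp(-(lam * t + extra_decay)))
    z = rng.standard_normal((n_tissues, 2))
    x = log2_mean + log2_sd * z[:, 0]
    y = log2_mean + log2_sd * (rho * z[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * z[:, 1])
    fpkm_a = np.power(2.0, x)
    fpkm_b = np.power(2.0, y)
    p_sil = silencing_probability(t, silencing_max, silencing_midpoint, silencing_width)
    for i in range(n_tissues):
        if rng.random() < p_sil:
            victim = int(rng.integers(0, 2))
            low = rng.uniform(0.0, 0.9)
            if victim == 0:
                fpkm_a[i] = low
            else:
                fpkm_b[i] = low
    return fpkm_a, fpkm_b


# ---------------------------------------------------------------------------
# Whole-study bundle

@dataclass
class StudyBundle:
    """File paths and in-memory truth for one simulated study."""

    out_dir: Path
    proteins_path: Path
    cds_path: Path
    gene_models_path: Path
    hits_path: Path
    lineage_path: Path
    expression_path: Path
    truth_path: Path
    truth: pd.DataFrame


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> StudyBundle:
    """Generate a full study bundle on disk.

    With ``alignment_scope="all_vs_all"`` the hit table contains every
    positive-scoring global alignment among all simulated proteins (so the
    identification stage can run exactly as it would on real data); with
    ``"within_pairs"`` only the true partners are aligned, which scales to
    thousands of pairs for the statistical stages that do not need the
    all-vs-all search.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    t_lo, t_hi = config.branch_length_range
    w_lo, w_hi = config.omega_range
    L_lo, L_hi = config.length_codons_range
    e_lo, e_hi = config.base_exons_range

    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    models: list[GeneModel] = []
    lineage: dict[str, bool] = {}
    expr_rows: dict[str, np.ndarray] = {}
    truth_rows: list[dict[str, object]] = []
    chrom_cursor: dict[str, int] = {}

    def chrom_name(i: int) -> str:
        return f"chr{i + 1}"

    for i in range(config.n_pairs):
        pair_id = f"p{i:04d}"
        ga, gb = f"g{i:04d}a", f"g{i:04d}b"
        t = float(rng.uniform(t_lo, t_hi))
        omega = float(rng.uniform(w_lo, w_hi))
        L = int(rng.integers(L_lo, L_hi + 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = simulate_cds_pair(L, t, omega, rng)
        prot_a, prot_b = translate_cds(sim.cds_a), translate_cds(sim.cds_b)

        intra = bool(rng.random() < config.intra_fraction)
        c1 = int(rng.integers(0, config.n_chromosomes))
        if intra:
            c2 = c1
        else:
            c2 = int(rng.integers(0, config.n_chromosomes - 1))
            if c2 >= c1:
                c2 += 1
        chrom_a, chrom_b = chrom_name(c1), chrom_name(c2)

        base_exons = int(rng.integers(e_lo, e_hi + 1))
        lengths = _partition_codons(L, base_exons, rng)
        specific = t < config.species_specific_t_max
        struct = simulate_structure_pair(
            base_exons, t, config.structure_event_rate, rng,
            base_lengths=lengths, gene_ids=(ga, gb),
            chromosomes=(chrom_a, chrom_b), lineage_specific=specific,
        )
        model_a = _relocate(struct.model_a, chrom_cursor)
        model_b = _relocate(struct.model_b, chrom_cursor)

        extra = config.sd_extra_decay if struct.events else 0.0
        fpkm_a, fpkm_b = simulate_expression_pair(
            t, config.expression_decay, config.tissue_count, rng,
            silencing_max=config.silencing_max,
            silencing_midpoint=config.silencing_midpoint,
            silencing_width=config.silencing_width,
            extra_decay=extra,
        )

        proteins.append(SequenceRecord(id=ga, kind="protein", residues=prot_a))
        proteins.append(SequenceRecord(id=gb, kind="protein", residues=prot_b))
        cds_records.append(SequenceRecord(id=ga, kind="cds", residues=sim.cds_a))
        cds_records.append(SequenceRecord(id=gb, kind="cds", residues=sim.cds_b))
        models.extend([model_a, model_b])
        lineage[ga] = specific
        lineage[gb] = specific
        expr_rows[ga] = fpkm_a
        expr_rows[gb] = fpkm_b
        n_gain_loss = sum(1 for e in struct.events if e.kind in {"gain", "loss"})
        n_shift = sum(1 for e in struct.events if e.kind == "shift")
        truth_rows.append(
            {
                "pair_id": pair_id,
                "gene_a": ga,
                "gene_b": gb,
                "t": t,
                "omega": omega,
                "length_codons": L,
                "true_dS": sim.true_dS,
                "true_dN": sim.true_dN,
                "n_structure_events": len(struct.events),
                "n_gain_loss_events": n_gain_loss,
                "n_shift_events": n_shift,
                "exon_count_a": model_a.n_exons,
                "exon_count_b": model_b.n_exons,
                "intra": intra,
                "lineage_specific": specific,
                "rho": float(np.exp(-(config.expression_decay * t + extra))),
            }
        )

    hits = _make_hits(proteins, truth_rows, config.alignment_scope)

    paths = StudyBundle(
        out_dir=out_dir,
        proteins_path=out_dir / "proteins.faa",
        cds_path=out_dir / "cds.fna",
        gene_models_path=out_dir / "gene_models.tsv",
        hits_path=out_dir / "hits.tsv",
        lineage_path=out_dir / "lineage.tsv",
        expression_path=out_dir / "expression.tsv",
        truth_path=out_dir / "truth.tsv",
        truth=pd.DataFrame(truth_rows),
    )
    write_fasta(proteins, paths.proteins_path)
    write_fasta(cds_records, paths.cds_path)
    write_gene_models_tsv(models, paths.gene_models_path)
    write_alignment_table(hits, paths.hits_path)
    write_lineage_table(lineage, paths.lineage_path)
    expr = pd.DataFrame.from_dict(expr_rows, orient="index",
                                  columns=list(config.tissue_names))
    expr.index.name = "gene_id"
    ExpressionMatrix(expr).to_tsv(paths.expression_path)
    paths.truth.to_csv(paths.truth_path, sep="\t", index=False)
    return paths


def _partition_codons(L: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split 3·L nucleotides into ``parts`` exon lengths, multiples of 3."""
    parts = min(parts, L)
    if parts == 1:
        return [3 * L]
    cuts = sorted(rng.choice(np.arange(1, L), size=parts - 1, replace=False).tolist())
    bounds = [0] + cuts + [L]
    return [3 * (b - a) for a, b in zip(bounds, bounds[1:])]


def _relocate(model: GeneModel, cursor: dict[str, int]) -> GeneModel:
    """Place a gene after the current end of its chromosome (no overlap)."""
    from dataclasses import replace

    offset = cursor.get(model.chromosome, 0) + 1000
    span = model.coding_exons[-1][1] - model.coding_exons[0][0]
    shift = offset - model.coding_exons[0][0]
    exons = tuple((s + shift, e + shift) for s, e in model.coding_exons)
    cursor[model.chromosome] = offset + span
    return replace(model, coding_exons=exons)


def _make_hits(proteins: list[SequenceRecord], truth_rows: list[dict[str, object]],
               scope: str):
    hits = []
    if scope == "within_pairs":
        by_id = {p.id: p for p in proteins}
        for row in truth_rows:
            a, b = str(row["gene_a"]), str(row["gene_b"])
            aln = align_proteins_global(by_id[a], by_id[b])
            fwd = alignment_to_hit(aln)
            hits.append(fwd)
            hits.append(
                type(fwd)(
                    query_id=fwd.subject_id, subject_id=fwd.query_id,
                    percent_identity=fwd.percent_identity,
                    aligned_length=fwd.aligned_length, bit_score=fwd.bit_score,
                )
            )
    else:
        for i, pa in enumerate(proteins):
            for pb in proteins[i + 1 :]:
                aln = align_proteins_global(pa, pb)
                if aln.score <= 0:
                    continue
                fwd = alignment_to_hit(aln)
                hits.append(fwd)
                hits.append(
                    type(fwd)(
                        query_id=fwd.subject_id, subject_id=fwd.query_id,
                        percent_identity=fwd.percent_identity,
                        aligned_length=fwd.aligned_length, bit_score=fwd.bit_score,
                    )
                )
    return hits
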