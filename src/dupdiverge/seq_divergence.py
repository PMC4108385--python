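"""Protein-guided codon alignment and dN/dS estimation for duplicate pairs.

The divergence estimator is a Nei–Gojobori (1986)-style counting method:

* synonymous/nonsynonymous *site* counts per codon are the per-position
  fractions of single-nucleotide changes that are synonymous, with changes
  that create stop codons excluded from the denominator (so every sense
  codon contributes exactly 3 sites);
* *differences* between a pair of aligned codons are counted by averaging
  the synonymous/nonsynonymous step counts over all minimal mutational
  pathways between them, pathways that pass through a stop codon excluded
  (all pathways weighted equally — unweighted NG86);
* the proportions pS = S_diffs/S_sites and pN = N_diffs/N_sites are
  corrected for multiple hits with the Jukes–Cantor formula
  d = −(3/4)·ln(1 − (4/3)·p).  p ≥ 3/4 is reported as saturated.

Protein alignment is global Needleman–Wunsch with BLOSUM62 scoring and
affine gaps (open −10, extend −0.5; a length-L gap costs
open + (L−1)·extend).  Sites are averaged over the two sequences, so the
estimate is exactly symmetric in its arguments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import AlignmentHit, SequenceRecord

__all__ = [
    "ProteinAlignment",
    "CodonAlignment",
    "DivergenceEstimate",
    "align_proteins_global",
    "project_to_codons",
    "estimate_dn_ds",
    "divergence_table",
    "alignment_to_hit",
    "GENETIC_CODE",
    "STOP_CODONS",
]

GAP_OPEN = -10.0
GAP_EXTEND = -0.5

_table = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
_NT = "ACGT"

_blosum62 = substitution_matrices.load("BLOSUM62")
_ALLOWED_AA = set(_blosum62.alphabet)


@dataclass(frozen=True)
class ProteinAlignment:
    """A global pairwise protein alignment with gap characters '-'."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_ungapped_columns(self) -> int:
        return sum(a != "-" and b != "-" for a, b in zip(self.aligned_a, self.aligned_b))

    @property
    def n_identical(self) -> int:
        return sum(a == b != "-" for a, b in zip(self.aligned_a, self.aligned_b))

    @property
    def identity(self) -> float:
        """Identical residues over ungapped (both-residue) columns."""
        n = self.n_ungapped_columns
        return self.n_identical / n if n else 0.0


@dataclass(frozen=True)
class CodonAlignment:
    """Codon columns projected from a protein alignment; None marks a gap."""

    id_a: str
    id_b: str
    columns: tuple[tuple[str | None, str | None], ...]

    @property
    def n_ungapped_codon_columns(self) -> int:
        return sum(a is not None and b is not None for a, b in self.columns)


@dataclass(frozen=True)
class DivergenceEstimate:
    """dS/dN and the site/difference counts behind them for one pair.

    ``dS``/``dN`` are NaN when the corresponding proportion is saturated
    (p ≥ 3/4), in which case ``saturated`` is True.
    """

    dS: float
    dN: float
    S_sites: float
    N_sites: float
    S_diffs: float
    N_diffs: float
    saturated: bool


def _new_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _blosum62
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_proteins_global(prot_a: SequenceRecord | str, prot_b: SequenceRecord | str,
                          id_a: str = "a", id_b: str = "b") -> ProteinAlignment:
    """Globally align two proteins (BLOSUM62, affine gaps −10/−0.5).

    Ties in the dynamic program are broken deterministically by taking the
    first optimal alignment in Biopython's canonical enumeration order.
    """
    if isinstance(prot_a, SequenceRecord):
        id_a, seq_a = prot_a.id, prot_a.residues.rstrip("*")
    else:
        seq_a = prot_a
    if isinstance(prot_b, SequenceRecord):
        id_b, seq_b = prot_b.id, prot_b.residues.rstrip("*")
    else:
        seq_b = prot_b
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty protein sequence")
    for name, seq in ((id_a, seq_a), (id_b, seq_b)):
        bad = set(seq) - _ALLOWED_AA
        if bad:
            raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")
    aligner = _new_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a_str, b_str = str(aln[0]), str(aln[1])
    return ProteinAlignment(id_a=id_a, id_b=id_b, aligned_a=a_str, aligned_b=b_str,
                            score=float(aln.score))


def alignment_to_hit(aln: ProteinAlignment) -> AlignmentHit:
    """Express a global alignment as a tabular hit (identity over ungapped columns)."""
    return AlignmentHit(
        query_id=aln.id_a,
        subject_id=aln.id_b,
        percent_identity=aln.identity,
        aligned_length=max(aln.n_ungapped_columns, 1),
        bit_score=aln.score,
    )


def project_to_codons(aln: ProteinAlignment, cds_a: SequenceRecord | str,
                      cds_b: SequenceRecord | str) -> CodonAlignment:
    """Back-translate a protein alignment onto the two coding sequences.

    Each aligned residue column becomes its source codon; a gap residue
    becomes a codon gap.  Terminal stop codons are trimmed before the
    length check; internal stops are errors.
    """
    def coding_of(cds: SequenceRecord | str, name: str) -> str:
        if isinstance(cds, SequenceRecord):
            return cds.coding
        seq = cds.upper()
        if len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        return seq

    seq_a = coding_of(cds_a, aln.id_a)
    seq_b = coding_of(cds_b, aln.id_b)
    for name, seq, aligned in ((aln.id_a, seq_a, aln.aligned_a), (aln.id_b, seq_b, aln.aligned_b)):
        n_res = sum(c != "-" for c in aligned)
        if len(seq) != 3 * n_res:
            raise ValueError(
                f"{name}: CDS length {len(seq)} does not match protein length {n_res} "
                f"(expected {3 * n_res} nt)"
            )
        for i in range(0, len(seq), 3):
            if seq[i : i + 3] in STOP_CODONS:
                raise ValueError(f"{name}: internal stop codon at nucleotide {i + 1}")

    columns: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for ra, rb in zip(aln.aligned_a, aln.aligned_b):
        ca = cb = None
        if ra != "-":
            ca = seq_a[3 * ia : 3 * ia + 3]
            ia += 1
        if rb != "-":
            cb = seq_b[3 * ib : 3 * ib + 3]
            ib += 1
        columns.append((ca, cb))
    return CodonAlignment(id_a=aln.id_a, id_b=aln.id_b, columns=tuple(columns))


# ---------------------------------------------------------------------------
# NG86 counting

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Per position, the fraction of one-nucleotide changes that are synonymous,
    with changes to stop codons excluded from the denominator; the two
    fractions at each position sum to 1, so S + N = 3 for every codon.
    """
    if codon in STOP_CODONS or codon not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    s_total = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_valid += 1
            if GENETIC_CODE[mutant] == aa:
                n_syn += 1
        if n_valid:
            s_total += n_syn / n_valid
    return s_total, 3.0 - s_total


@lru_cache(maxsize=None)
def codon_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Averages step classifications over all minimal mutational pathways,
    excluding pathways through stop codons; if every pathway is blocked
    (which cannot occur for ≤2 differences under the standard code), all
    pathways are used.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in GENETIC_CODE:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        syn = non = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                non += 1
            current = nxt
        return float(syn), float(non)

    orders = list(itertools.permutations(diff_pos))
    results = [r for r in (walk(o) for o in orders) if r is not None]
    if not results:
        results = []
        for order in orders:
            syn = non = 0
            current = codon_a
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt not in STOP_CODONS and GENETIC_CODE.get(current) == GENETIC_CODE.get(nxt):
                    syn += 1
                else:
                    non += 1
                current = nxt
            results.append((float(syn), float(non)))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; NaN when p ≥ 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def estimate_dn_ds(ca: CodonAlignment) -> DivergenceEstimate:
    """NG86 dN/dS estimate over the ungapped codon columns of an alignment."""
    S_a = S_b = 0.0
    S_diffs = N_diffs = 0.0
    n_cols = 0
    for codon_a, codon_b in ca.columns:
        if codon_a is None or codon_b is None:
            continue
        n_cols += 1
        sa, _ = codon_site_counts(codon_a)
        sb, _ = codon_site_counts(codon_b)
        S_a += sa
        S_b += sb
        sd, nd = codon_diff_counts(codon_a, codon_b)
        S_diffs += sd
        N_diffs += nd
    if n_cols == 0:
        raise ValueError(f"{ca.id_a}/{ca.id_b}: no ungapped codon columns")
    S_sites = (S_a + S_b) / 2.0
    N_sites = 3.0 * n_cols - S_sites
    pS = S_diffs / S_sites if S_sites > 0 else 0.0
    pN = N_diffs / N_sites if N_sites > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    saturated = math.isnan(dS) or math.isnan(dN)
    return DivergenceEstimate(
        dS=dS, dN=dN, S_sites=S_sites, N_sites=N_sites,
        S_diffs=S_diffs, N_diffs=N_diffs, saturated=saturated,
    )


def pair_divergence(prot_a: SequenceRecord, prot_b: SequenceRecord,
                    cds_a: SequenceRecord, cds_b: SequenceRecord) -> DivergenceEstimate:
    """Align, project and estimate in one call for a single pair."""
    aln = align_proteins_global(prot_a, prot_b)
    ca = project_to_codons(aln, cds_a, cds_b)
    return estimate_dn_ds(ca)


def divergence_table(pairs: Iterable[tuple[str, str]],
                     proteins: Mapping[str, SequenceRecord],
                     cds: Mapping[str, SequenceRecord]) -> pd.DataFrame:
    """Per-pair divergence estimates; failures are recorded, not fatal.

    Returns a DataFrame indexed by (gene_a, gene_b) with columns
    dS, dN, S_sites, N_sites, S_diffs, N_diffs, saturated, error.
    """
    rows = []
    for gene_a, gene_b in pairs:
        row: dict[str, object] = {"gene_a": gene_a, "gene_b": gene_b}
        try:
            for name in (gene_a, gene_b):
                if name not in proteins:
                    raise KeyError(f"protein {name!r} missing")
                if name not in cds:
                    raise KeyError(f"CDS {name!r} missing")
            est = pair_divergence(proteins[gene_a], proteins[gene_b], cds[gene_a], cds[gene_b])
            row.update(
                dS=est.dS, dN=est.dN, S_sites=est.S_sites, N_sites=est.N_sites,
                S_diffs=est.S_diffs, N_diffs=est.N_diffs, saturated=est.saturated, error="",
            )
        except (ValueError, KeyError) as exc:
            row.update(
                dS=np.nan, dN=np.nan, S_sites=np.nan, N_sites=np.nan,
                S_diffs=np.nan, N_diffs=np.nan, saturated=True, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index(["gene_a", "gene_b"])
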