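# dupdiverge

Duplicate genes — paralog pairs created by gene duplication — diverge over
time in three coupled ways: their coding sequences accumulate synonymous
(dS) and nonsynonymous (dN) substitutions, their exon–intron structures
drift apart, and their tissue-expression profiles decorrelate.
`dupdiverge` is a tested, reusable pipeline for analysing all three axes in
a single genome, of the kind used in genome-wide paralog surveys (the
bundled reference counts come from the bovine genome). It is aimed at
comparative genomicists who have a proteome, coding sequences, gene models
and a gene × tissue FPKM matrix and want the complete duplicate-gene
divergence analysis without external services.

## What it computes

**Duplicate pair identification.** All-vs-all protein hits (BLAST
`-outfmt 6` tables, or the in-repo global aligner at desk scale) are
reduced to reciprocal best hits; a pair is called a duplicate when the
aligned region covers ≥ 80% of the longer protein and its identity *I*
exceeds a length-dependent homology threshold

> I ≥ 0.30 for aligned length L > 150 aa,
> I ≥ 0.01·n + 4.8·L^(−0.32·(1 + e^(−L/1000))) (n = 6) otherwise.

Pseudogene pairs are discarded; pairs are classified intra- vs
interchromosomal and species-specific (neither gene has a recorded homolog
outside the focal species) vs shared, then summarized per chromosome as
duplicate content (percent of genes in ≥ 1 pair).

**Sequence divergence.** Proteins are aligned globally (Needleman–Wunsch,
BLOSUM62, affine gaps −10/−0.5), the alignment is projected onto codons,
and dN/dS are estimated by Nei–Gojobori counting: per-codon synonymous
site fractions (stop-codon changes excluded), pathway-averaged difference
counts, and the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p), with
p ≥ 3/4 flagged as saturated.

**Structural divergence.** Class 1 = different numbers of coding exons;
Class 2 = equal counts but at least one positionally homologous exon pair
(matched in transcription order) differs in length.

**Expression divergence.** A gene is off in a tissue at FPKM < 1, on at
FPKM > 2; a pair diverges in a tissue when one gene is on and the other
off. Profile similarity is Pearson's r of log2(FPKM + 1) across tissues,
analysed on the variance-stabilized scale T(r) = ln((1 + r)/(1 − r)).

**Linking statistics.** Rank-binned trends of structural divergence and of
T(r) against dS; Wilcoxon rank-sum comparison of T(r) between structurally
divergent (SD) and non-divergent (NSD) pairs; common-slope ANCOVA
T(r) ~ dS + SD testing the structure effect while controlling for
synonymous divergence; identity-distribution and chromosome-distribution
tests.

A synthetic-data generator produces full study bundles (FASTA, gene-model
TSV, hit table, lineage table, expression TSV, truth table) under a codon
substitution model with tunable dS/dN, Poisson exon-structure events and
time-decaying expression correlation, so every stage is testable end to
end with known truth.

## Worked example

```python
import json
from dupdiverge import SimulationConfig, simulate_study, PipelineConfig, run_pipeline

bundle = simulate_study(
    SimulationConfig(seed=7, n_pairs=50, alignment_scope="all_vs_all"), "demo")
config = PipelineConfig(
    proteins=str(bundle.proteins_path), cds=str(bundle.cds_path),
    gene_models=str(bundle.gene_models_path), hits=str(bundle.hits_path),
    expression=str(bundle.expression_path), lineage=str(bundle.lineage_path),
    out_dir="demo_out", structure_bin_size=10)
outputs = run_pipeline(config)
```

Inspecting the outputs of this exact run prints:

```
pairs identified: 50
intra fraction: 0.42
median dS: 0.149
structure-vs-dS bin correlation r=0.82 p=0.087
fraction divergent in >=1 tissue: 0.82
ANCOVA structure coefficient: -0.53 (p=0.348)
```

All 50 simulated duplicate pairs are recovered by the reciprocal-best-hit
criteria. The five-bin structure trend is strongly positive but, at 50
pairs, not yet significant, and the ANCOVA structure coefficient is
negative (SD pairs less correlated in expression) but noisy — both sharpen
into clear signals at the 2000-pair scale used by the acceptance script.
Stage tables (`pairs.tsv`, `divergence.tsv`, `structure.tsv`,
`expression.tsv`, `stats.json`, …) and a reproducibility manifest are
written to `demo_out/`.

The same stages are available from the shell:

```bash
dupdiverge simulate --seed 7 --n-pairs 50 --out demo
dupdiverge run --config config.yaml
dupdiverge identify --proteins p.faa --models g.tsv --hits h.tsv --out pairs.tsv
```

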