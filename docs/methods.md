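# Methods

This note documents the models, conventions and numerical choices behind
`dupdiverge`, and what the synthetic-data tests do and do not demonstrate.

## Duplicate identification

Candidates are reciprocal best hits (RBH) over an all-vs-all protein hit
table. Per ordered (query, subject) pair only the top-scoring HSP is used;
the best subject per query is chosen by bit score, breaking ties by higher
identity and then lexicographically smaller subject id. The deterministic
tie-break is our choice: RBH is otherwise order-dependent on tied inputs
and the pipeline promises byte-identical reruns.

A candidate pair becomes a duplicate when

* coverage: aligned length ≥ `min_coverage` (default 0.8) × the longer
  protein's length, and
* identity ≥ I_min(L), with I_min(L) = `long_identity` (default 0.30) for
  L > 150 aa and I_min(L) = 0.01·n + 4.8·L^(−0.32·(1 + e^(−L/1000)))
  (n = 6) for shorter alignments — the classic length-scaled homology
  threshold for short alignments. All constants are `DuplicateCriteria`
  fields, so alternative thresholds are one-line changes.

Pairs touching any biotype containing "pseudogene" are dropped. A pair is
*species-specific* only when **both** genes lack a recorded homolog outside
the focal species — the conservative reading of a lineage flag table.
Chromosome summaries count **genes**, not pairs: a gene belongs to the
intra (inter) column of its chromosome if it participates in ≥ 1 intra
(inter) pair, and to both columns if it does both. Duplicate content is
100 × duplicate genes / genes.

## Sequence divergence

Protein alignment is global Needleman–Wunsch with BLOSUM62, gap open −10
and extension −0.5, where a length-L gap costs open + (L−1)·extend.
Biopython's `PairwiseAligner` provides the dynamic program; the test suite
checks its scores against an independent memoized Gotoh recursion. Ties
between co-optimal alignments are resolved by taking the first alignment
in the aligner's canonical enumeration order; only the codon columns, not
the path choice, affect downstream counts in the no-indel simulations.

The alignment is projected column-by-column onto the coding sequences
(gap residue → codon gap). Terminal stop codons are trimmed before the
3 × protein-length check; internal stops are errors.

dN/dS uses Nei–Gojobori (1986) counting:

* **Sites.** Per codon position, the fraction of the ≤ 3 single-nucleotide
  changes that are synonymous, with changes producing stop codons removed
  from the denominator. The synonymous and nonsynonymous fractions at a
  position sum to 1, so every codon contributes exactly 3 sites
  (S_sites + N_sites = 3 × ungapped columns). Site counts are averaged
  over the two sequences, making the estimate exactly symmetric.
* **Differences.** For a codon pair differing at k positions, all k!
  minimal mutational pathways are enumerated; pathways through stop codons
  are excluded and the rest weighted equally (unweighted NG86). If every
  pathway were blocked — impossible for k ≤ 2 under the standard code —
  all pathways would be used as a fallback.
* **Correction.** pS = S_diffs/S_sites and pN = N_diffs/N_sites are
  corrected with Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p); p ≥ 3/4 sets
  the saturated flag and reports that distance as missing.

Counting replaces likelihood optimization deliberately: the downstream
analyses use dS and dN only ordinally (ranking, binning, regression),
where counting and ML estimates agree closely at moderate divergence, and
counting is dependency-free and exactly reproducible. An external ML
estimator can be substituted behind `divergence_table` if needed.

## Structural divergence

Exon *lengths* are end − start + 1 on 1-based inclusive coordinates (the
GFF3 convention is the internal standard throughout; BED-style inputs are
not supported). Class 1 = unequal exon counts. With equal counts, exons
are matched positionally in transcription order — genomic order reversed
on the minus strand — and any length inequality is Class 2. Positional
matching is the only definition consistent with a count-and-length
comparison; no attempt is made to map intron positions onto the protein
alignment. Coding exons (CDS segments) are compared because the proteins
define the pairs; gene models built from full exons can be supplied to get
the UTR-inclusive variant.

The trend against dS ranks pairs (saturated excluded), forms consecutive
bins of `structure_bin_size` (default 200 pairs, the resolution used in
genome-scale surveys; the trailing partial bin is dropped), and reports
the Pearson correlation of per-bin mean dS with per-bin divergent
proportion. With fewer than two full bins the trend is an error; with a
constant proportion the correlation is reported as undefined (NaN).

## Expression divergence

States on raw FPKM: off < 1, on > 2, the 1–2 interval ambiguous.
Ambiguous states never count as divergence (a conservative reading of an
on/off definition that leaves the gap unspecified). A pair diverges in a
tissue when one gene is on and the other off. Similarity is Pearson's r
across tissues of log2(FPKM + offset), offset 1.0 (a raw-scale option
exists); r is undefined when either profile is constant. The transform
T(r) = ln((1 + r)/(1 − r)) is applied with |r| clamped to 1 − 10⁻⁶, since
T diverges at |r| = 1. Only pairs with both genes on in ≥ 1 tissue enter
correlation analyses (`min_tissues_expressed` raises this gate, e.g. to 3
for the robustness variant).

Binned regression of T(r) on dS (or dN) uses bins of
`expression_bin_size` (default 5 pairs); bin size 1 reduces exactly to
the unbinned OLS. For dN the fit is run separately below and above
`dn_split` (default 0.3) to separate the nearly-neutral from the
constrained regime.

## Linking statistics

Group comparisons use the two-sided Wilcoxon rank-sum (exact null for
groups ≤ 25 without ties); distribution comparisons add two-sample
Kolmogorov–Smirnov; chromosome heterogeneity is a chi-square goodness of
fit against expectation proportional to gene counts (smallest cells merged
below expected count 1); intra-vs-inter excess per chromosome is an exact
binomial test against the genome-wide intra fraction. These are standard
nonparametric choices; the analyses report raw p-values (a
Benjamini–Hochberg helper exists but is off by default).

The ANCOVA is the common-slope linear model T(r) ~ β₀ + β₁·dS + β₂·SD,
with β₂ the structure effect controlling for synonymous divergence; an
interaction term is available behind a flag. A single-class design is a
rank-deficient error. **Caveat:** under the generator's mechanism T(r) is
nonlinear in dS (≈ 2·atanh(e^(−λt))) while the SD indicator also tracks t,
so a linear dS control is imperfect and β₂ can be nonzero without any
direct structure→expression coupling. Parameter-recovery tests therefore
inject an additive class effect in a linear generative model on the
simulated design; mechanism-level coupling (`sd_extra_decay`) is used only
for direction/significance checks.

## Synthetic data generator

Per pair, a divergence-time scale t (expected proposed nucleotide changes
per codon, both copies combined) drives all three axes:

* **Sequence** — uniform sense-codon ancestor; each copy receives
  Poisson(L·t/2) proposed point mutations with equal nucleotide exchange
  rates; synonymous proposals are accepted, nonsynonymous accepted with
  probability ω, stop-creating proposals rejected (a minimal
  Goldman–Yang-flavoured scheme — enough to create the dS/dN gradients the
  analyses consume, without a full substitution-matrix simulator). The
  realized accepted-event counts divided by the ancestor's NG86 site
  counts are returned as true dS/dN for recovery tests. The exact RNG draw
  order is documented in `simulate_cds_pair` so replay oracles can verify
  it step by step.
* **Structure** — Poisson(rate·t) events: exon gain, exon loss (only when
  > 1 exon remains) or a frame-preserving ±3k-nt boundary shift, applied
  to a random copy; exon lengths stay multiples of 3 and ≥ 3 nt.
* **Expression** — per-tissue log2 levels bivariate normal
  (mean 3, sd 2) with correlation ρ = e^(−λt); tissue silencing (FPKM
  forced below 1 in one copy) with logistic probability
  p_max/(1 + e^(−(t − t₀)/w)). The logistic shape is our choice — the
  on/off mechanism is observed, not modelled, in real surveys — with all
  shape parameters config-exposed.

Defaults emulate a seven-tissue mammalian survey: ~31% intrachromosomal
pairs, t ∈ [0.02, 1.0] spanning near-identity to near-saturation,
ω ∈ [0.05, 0.5], structure-event rate 8 per unit t (≈ 90% of pairs
divergent overall and ≈ 87% at the species-specific cutoff t < 0.25),
expression decay λ = 1, silencing p_max = 0.4, t₀ = 0.3, w = 0.15 (per-
tissue divergence fractions around 20%). All randomness flows through one
seeded PCG64 generator; a fixed seed yields byte-identical bundles.

`alignment_scope="all_vs_all"` computes the full positive-scoring global
alignment table (used for end-to-end identification fixtures, ~50 pairs);
`"within_pairs"` aligns only true partners, which scales to thousands of
pairs for the statistical stages that never consult non-partner hits.

What the generator does **not** emulate — hence what passing tests cannot
show about real data: no indels within exons (protein alignments are
unambiguous, so codon projection is never stressed by misalignment), no
rate heterogeneity among sites or transition/transversion bias (the JC
correction is exactly matched to the proposal process), gene-model exon
layouts are not kept consistent with the evolved CDS lengths, expression
is noise-free FPKM rather than replicate-based estimates, and gene
families are strictly pairs (no multi-copy families competing in RBH).

## Problem sizes and determinism

The test suite runs end-to-end on 50-pair bundles, oracle comparisons on
all 61 sense codons × all codon pairs and on 100 random 150-codon pairs,
parameter recovery on 200 pairs, trend/ANCOVA checks on a 2000-pair
bundle, and null calibration over 200 replicates — sizes at which every
check is stable across seeds while the whole suite stays interactive.
All stochastic tests are seeded; pipeline reruns with the same config are
byte-identical (the manifest records config hash, versions and seed).

## Known limitations

* NG86 counting underestimates dS relative to ML methods at high
  divergence and ignores codon-frequency bias; saturated pairs are
  reported as missing rather than extrapolated.
* Identity/coverage from the in-repo global aligner differ slightly from
  BLAST local HSPs (identity is computed over both-residue columns of the
  global alignment); at desk scale this only matters near the thresholds.
* One protein/exon structure per gene: multi-isoform genes are collapsed
  to the longest CDS transcript, the common convention for paralog
  analyses.
* The common-slope ANCOVA controls for dS linearly; see the caveat above.
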