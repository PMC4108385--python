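import itertools

import numpy as np
import pytest

import oracles
from dupdiverge.dup_identify import (
    DuplicateCriteria,
    DuplicatePair,
    apply_duplicate_criteria,
    classify_pairs,
    filter_pseudogenes,
    identify_duplicates,
    reciprocal_best_hits,
    summarize_by_chromosome,
)
from dupdiverge.io_formats import AlignmentHit, GeneModel, SequenceRecord
from dupdiverge.reference_tables import build_genome_fixture, published_contents


def hit(q, s, bits, ident=0.9, length=200):
    return AlignmentHit(query_id=q, subject_id=s, percent_identity=ident,
                        aligned_length=length, bit_score=bits)


def model(gid, chrom="1", biotype="protein_coding", specific=False):
    return GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                     coding_exons=((101, 400),), biotype=biotype,
                     lineage_specific=specific)


def protein(gid, length=200):
    return SequenceRecord(id=gid, kind="protein", residues="M" + "K" * (length - 1))


class TestReciprocalBestHits:
    def test_mutual_best_pair_kept(self):
        pairs = reciprocal_best_hits([hit("a", "b", 300), hit("b", "a", 300)])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]

    def test_non_mutual_best_rejected(self):
        hits = [hit("a", "b", 300), hit("b", "a", 100), hit("b", "c", 300),
                hit("c", "b", 300)]
        pairs = reciprocal_best_hits(hits)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("b", "c")]

    def test_top_hsp_only_considered_per_ordered_pair(self):
        hits = [hit("a", "b", 100), hit("a", "b", 400), hit("a", "c", 300),
                hit("b", "a", 400), hit("c", "a", 300)]
        pairs = reciprocal_best_hits(hits)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]

    def test_random_tables_match_enumeration_oracle(self, rng):
        genes = list("abcdef")
        for _ in range(30):
            hits = []
            for q, s in itertools.permutations(genes, 2):
                if rng.random() < 0.7:
                    hits.append(hit(q, s, bits=float(rng.integers(1, 6)) * 50,
                                    ident=round(float(rng.uniform(0.3, 1.0)), 2)))
            got = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(hits)}
            assert got == oracles.rbh_oracle(hits)

    def test_no_gene_has_two_partners(self, rng):
        genes = [f"g{i}" for i in range(10)]
        hits = [hit(q, s, bits=float(rng.integers(1, 500)))
                for q, s in itertools.permutations(genes, 2)]
        pairs = reciprocal_best_hits(hits)
        seen = [g for p in pairs for g in p.key]
        assert len(seen) == len(set(seen))


class TestDuplicateCriteria:
    def test_long_alignment_passes(self):
        pairs = [DuplicatePair("a", "b", identity=0.95, aligned_length=200)]
        prot = {"a": protein("a", 220), "b": protein("b", 210)}
        assert apply_duplicate_criteria(pairs, prot) != []

    def test_coverage_boundary_rejects(self):
        # aligned 158 of longer 200 = 0.79 coverage
        pairs = [DuplicatePair("a", "b", identity=0.95, aligned_length=158)]
        prot = {"a": protein("a", 200), "b": protein("b", 180)}
        assert apply_duplicate_criteria(pairs, prot) == []

    def test_short_alignment_uses_length_scaled_curve(self):
        crit = DuplicateCriteria()
        # direct numeric evaluation of the published threshold expression
        L = 100
        expected = 0.06 + 4.8 * L ** (-0.32 * (1 + np.exp(-L / 1000)))
        assert crit.min_identity(100) == pytest.approx(expected)
        pairs = [DuplicatePair("a", "b", identity=0.31, aligned_length=100)]
        prot = {"a": protein("a", 110), "b": protein("b", 105)}
        kept = apply_duplicate_criteria(pairs, prot)
        assert (kept != []) == (0.31 >= expected)
        assert kept == []  # I_min(100) ≈ 0.35 > 0.31

    def test_threshold_constant_above_150(self):
        crit = DuplicateCriteria()
        assert crit.min_identity(151) == 0.30
        assert crit.min_identity(150) > 0.30

    def test_missing_protein_is_error(self):
        pairs = [DuplicatePair("a", "b", identity=0.9, aligned_length=200)]
        with pytest.raises(KeyError, match="b"):
            apply_duplicate_criteria(pairs, {"a": protein("a")})

    def test_raising_thresholds_never_adds_pairs(self, rng):
        prot = {f"g{i}": protein(f"g{i}", int(rng.integers(80, 300))) for i in range(20)}
        pairs = []
        for i in range(0, 20, 2):
            a, b = f"g{i}", f"g{i+1}"
            length = int(0.7 * max(len(prot[a].residues), len(prot[b].residues))
                         + rng.integers(0, 100))
            pairs.append(DuplicatePair(*sorted((a, b)),
                                       identity=round(float(rng.uniform(0.2, 1.0)), 2),
                                       aligned_length=length))
        base = {p.key for p in apply_duplicate_criteria(pairs, prot)}
        for cov, ident in ((0.85, 0.30), (0.9, 0.45), (0.95, 0.6)):
            crit = DuplicateCriteria(min_coverage=cov, long_identity=ident,
                                     curve_n=ident * 100)
            stricter = {p.key for p in apply_duplicate_criteria(pairs, prot, crit)}
            assert stricter <= base


class TestFiltersAndClasses:
    def test_pseudogene_pairs_removed(self):
        pairs = [DuplicatePair("a", "b", 0.9, 200), DuplicatePair("c", "d", 0.9, 200)]
        models = {"a": model("a"), "b": model("b", biotype="processed_pseudogene"),
                  "c": model("c"), "d": model("d")}
        kept = filter_pseudogenes(pairs, models)
        assert [(p.gene_a, p.gene_b) for p in kept] == [("c", "d")]

    def test_no_pseudogenes_is_identity(self):
        pairs = [DuplicatePair("a", "b", 0.9, 200)]
        models = {"a": model("a"), "b": model("b")}
        assert filter_pseudogenes(pairs, models) == pairs

    def test_mixed_fixture_counts(self):
        pairs, models = [], {}
        for i in range(10):
            a, b = f"a{i}", f"b{i}"
            pairs.append(DuplicatePair(a, b, 0.9, 200))
            flagged = i < 3
            models[a] = model(a, biotype="pseudogene" if flagged else "protein_coding")
            models[b] = model(b)
        assert len(filter_pseudogenes(pairs, models)) == 7

    def test_unknown_gene_is_error(self):
        with pytest.raises(KeyError):
            filter_pseudogenes([DuplicatePair("a", "b", 0.9, 200)], {"a": model("a")})

    def test_locality_and_lineage_classification(self):
        pairs = [DuplicatePair("a", "b", 0.9, 200), DuplicatePair("c", "d", 0.9, 200)]
        models = {"a": model("a", "5", specific=True), "b": model("b", "5", specific=True),
                  "c": model("c", "5", specific=True), "d": model("d", "7", specific=False)}
        out = classify_pairs(pairs, models)
        assert (out[0].locality, out[0].lineage) == ("intra", "species_specific")
        assert (out[1].locality, out[1].lineage) == ("inter", "shared")

    def test_simulated_bundle_locality_agrees_with_truth(self, bundle50):
        from dupdiverge.io_formats import (
            read_alignment_table, read_fasta, read_gene_models,
        )

        prot = {r.id: r for r in read_fasta(bundle50.proteins_path, kind="protein")}
        models = {m.gene_id: m for m in read_gene_models(bundle50.gene_models_path)}
        pairs = identify_duplicates(
            read_alignment_table(bundle50.hits_path), prot, models,
        )
        truth = {
            (r.gene_a, r.gene_b): "intra" if r.intra else "inter"
            for r in bundle50.truth.itertuples()
        }
        matched = [p for p in pairs if p.key in truth]
        assert matched
        assert all(p.locality == truth[p.key] for p in matched)


class TestChromosomeSummary:
    def test_hand_enumerated_three_chromosome_fixture(self):
        models = {}
        for gid, chrom in [("a", "1"), ("b", "1"), ("c", "1"), ("d", "2"),
                           ("e", "2"), ("f", "3"), ("g", "3"), ("h", "3")]:
            models[gid] = model(gid, chrom)
        pairs = classify_pairs(
            [DuplicatePair("a", "b", 0.9, 200),   # intra chr1
             DuplicatePair("c", "d", 0.9, 200)],  # inter chr1-chr2
            models,
        )
        summaries, genome, table = summarize_by_chromosome(pairs, models)
        by_chrom = {s.chromosome: s for s in summaries}
        assert by_chrom["1"].n_dup_genes_intra == 2
        assert by_chrom["1"].n_dup_genes_inter == 1
        assert by_chrom["2"].n_dup_genes_inter == 1
        assert by_chrom["3"].n_dup_genes == 0
        assert by_chrom["1"].duplicate_content == pytest.approx(100.0)
        assert by_chrom["3"].duplicate_content == 0.0
        assert genome.n_genes == 8
        assert genome.duplicate_content == pytest.approx(100 * 4 / 8)

    def test_zero_pairs_gives_zero_content(self):
        models = {"a": model("a")}
        summaries, genome, _ = summarize_by_chromosome([], models)
        assert summaries[0].duplicate_content == 0.0

    def test_published_genome_counts_reproduced(self):
        models, pairs = build_genome_fixture()
        summaries, genome, _ = summarize_by_chromosome(pairs, models)
        pub = published_contents()
        for s in list(summaries) + [genome]:
            want_all, want_specific = pub[s.chromosome]
            assert round(s.duplicate_content, 1) == want_all, s.chromosome
            assert round(s.specific_content, 1) == want_specific, s.chromosome
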