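import math

import numpy as np
import pytest
from scipy import stats as sps

import oracles
from dupdiverge.divergence_stats import (
    ancova_structure_expression,
    benjamini_hochberg,
    chromosome_distribution_test,
    compare_sd_nsd,
    identity_distribution_tests,
)
from dupdiverge.dup_identify import (
    ChromosomeSummary,
    DuplicatePair,
    classify_pairs,
    summarize_by_chromosome,
)
from dupdiverge.expression_divergence import ExpressionComparison
from dupdiverge.reference_tables import build_genome_fixture
from dupdiverge.structure_divergence import StructureComparison


def expr_cmp(a, b, transformed_r, eligible=True):
    return ExpressionComparison(
        gene_a=a, gene_b=b, states_a=("on",) * 7, states_b=("on",) * 7,
        n_divergent_tissues=0, r=math.tanh(transformed_r / 2),
        transformed_r=transformed_r, eligible=eligible,
        n_tissues_expressed_a=7, n_tissues_expressed_b=7,
    )


def struct_cmp(a, b, divergent):
    return StructureComparison(
        gene_a=a, gene_b=b, n_exons_a=3, n_exons_b=3 if not divergent else 4,
        structure_class="class1" if divergent else "identical",
    )


def make_rows(values_sd, values_nsd):
    comps, structs = [], []
    for i, v in enumerate(values_sd):
        a, b = f"s{i}a", f"s{i}b"
        comps.append(expr_cmp(a, b, v))
        structs.append(struct_cmp(a, b, True))
    for i, v in enumerate(values_nsd):
        a, b = f"n{i}a", f"n{i}b"
        comps.append(expr_cmp(a, b, v))
        structs.append(struct_cmp(a, b, False))
    return comps, structs


class TestCompareSdNsd:
    def test_exact_p_matches_permutation_enumeration(self):
        sd_vals = [0.1, 0.9, 1.4, 2.2]
        nsd_vals = [1.1, 1.9, 2.5, 3.0]
        comps, structs = make_rows(sd_vals, nsd_vals)
        out = compare_sd_nsd(comps, structs)
        (contrast,) = out.contrasts
        assert contrast.p_value == pytest.approx(
            oracles.ranksum_exact_p(nsd_vals, sd_vals)
        )

    def test_single_pair_groups_use_exact_method(self):
        comps, structs = make_rows([0.5], [1.5])
        out = compare_sd_nsd(comps, structs)
        (contrast,) = out.contrasts
        assert 0.0 < contrast.p_value <= 1.0
        assert contrast.p_value == pytest.approx(1.0)  # 1 vs 1: both orders equally likely

    def test_lower_sd_values_detected(self, rng):
        sd_vals = list(rng.normal(-1.0, 1.0, 80))
        nsd_vals = list(rng.normal(0.5, 1.0, 80))
        comps, structs = make_rows(sd_vals, nsd_vals)
        out = compare_sd_nsd(comps, structs)
        by = {g.label: g for g in out.groups}
        assert by["SD"].mean < by["NSD"].mean
        assert out.contrasts[0].p_value < 0.05

    def test_empty_group_skips_contrast_with_warning(self):
        comps, structs = make_rows([0.5, 0.7], [])
        with pytest.warns(UserWarning, match="empty group"):
            out = compare_sd_nsd(comps, structs)
        assert out.contrasts == ()


class TestAncova:
    def _simulate(self, rng, n, effect):
        comps, structs, ds = [], [], {}
        for i in range(n):
            a, b = f"g{i}a", f"g{i}b"
            x = float(rng.uniform(0, 1))
            sd = bool(rng.random() < 0.5)
            y = 2.0 - 1.5 * x + (effect if sd else 0.0) + float(rng.normal(0, 0.5))
            comps.append(expr_cmp(a, b, y))
            structs.append(struct_cmp(a, b, sd))
            ds[(a, b)] = x
        return comps, structs, ds

    def test_null_effect_within_three_se(self, rng):
        comps, structs, ds = self._simulate(rng, 400, effect=0.0)
        res = ancova_structure_expression(comps, structs, ds)
        assert abs(res.structure_coef) < 3 * res.structure_se

    def test_injected_effect_recovered(self, rng):
        comps, structs, ds = self._simulate(rng, 1000, effect=-0.5)
        res = ancova_structure_expression(comps, structs, ds)
        assert abs(res.structure_coef - (-0.5)) < 3 * res.structure_se
        assert res.structure_p < 0.05
        assert res.n_sd + res.n_nsd == 1000

    def test_per_class_lines_equal_closed_form_ols(self):
        # hand-set points: NSD on y = 1 - 2x exactly; SD on y = 0.5 - x + tiny wiggle
        comps, structs, ds = [], [], {}
        pts_nsd = [(0.0, 1.0), (0.5, 0.0), (1.0, -1.0)]
        pts_sd = [(0.0, 0.5), (0.4, 0.1), (0.8, -0.3), (1.0, -0.5)]
        for i, (x, y) in enumerate(pts_nsd):
            a, b = f"n{i}a", f"n{i}b"
            comps.append(expr_cmp(a, b, y)); structs.append(struct_cmp(a, b, False))
            ds[(a, b)] = x
        for i, (x, y) in enumerate(pts_sd):
            a, b = f"s{i}a", f"s{i}b"
            comps.append(expr_cmp(a, b, y)); structs.append(struct_cmp(a, b, True))
            ds[(a, b)] = x
        res = ancova_structure_expression(comps, structs, ds)

        def ols(pts):
            xs = np.array([p[0] for p in pts]); ys = np.array([p[1] for p in pts])
            slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / ((xs - xs.mean()) ** 2).sum()
            return slope, ys.mean() - slope * xs.mean()

        assert res.line_nsd == pytest.approx(ols(pts_nsd))
        assert res.line_sd == pytest.approx(ols(pts_sd))

    def test_single_class_design_is_error(self, rng):
        comps, structs, ds = self._simulate(rng, 50, effect=0.0)
        structs_all_sd = [struct_cmp(s.gene_a, s.gene_b, True) for s in structs]
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_structure_expression(comps, structs_all_sd, ds)


class TestIdentityDistributions:
    def _pairs(self, identities, lineage=None, locality=None):
        out = []
        for i, ident in enumerate(identities):
            out.append(DuplicatePair(
                gene_a=f"p{i:04d}a", gene_b=f"p{i:04d}b", identity=float(ident),
                aligned_length=200,
                locality=locality[i] if locality else ("intra" if i % 2 else "inter"),
                lineage=lineage[i] if lineage else "shared",
            ))
        return out

    def test_identical_groups_have_zero_ks(self, rng):
        vals = list(rng.uniform(0.3, 1.0, 40))
        lineage = ["species_specific"] * 40
        pairs = self._pairs(vals + vals, lineage=lineage + ["shared"] * 40)
        out = identity_distribution_tests(pairs)
        assert out["species_specific_vs_all"]["ks_statistic"] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_right_shifted_specific_identities_detected(self, rng):
        # species-specific pairs diverged more recently: higher identity
        shared = np.clip(rng.normal(0.55, 0.12, 300), 0.3, 1.0)
        specific = np.clip(rng.normal(0.85, 0.08, 200), 0.3, 1.0)
        pairs = self._pairs(
            list(shared) + list(specific),
            lineage=["shared"] * 300 + ["species_specific"] * 200,
        )
        out = identity_distribution_tests(pairs)
        assert out["species_specific_vs_all"]["median_a"] > out["species_specific_vs_all"]["median_b"]
        assert out["species_specific_vs_all"]["ranksum_p"] < 0.05
        assert out["species_specific_vs_all"]["ks_p"] < 0.05

    def test_rank_sum_matches_enumeration_oracle(self):
        intra = [0.95, 0.9, 0.7, 0.8]
        inter = [0.6, 0.65, 0.85, 0.5]
        pairs = self._pairs(intra + inter,
                            locality=["intra"] * 4 + ["inter"] * 4,
                            lineage=["species_specific"] * 2 + ["shared"] * 6)
        out = identity_distribution_tests(pairs)
        assert out["intra_vs_inter"]["ranksum_p"] == pytest.approx(
            oracles.ranksum_exact_p(intra, inter), abs=0.02
        )

    def test_too_small_group_is_error(self):
        pairs = self._pairs([0.9, 0.8], lineage=["species_specific", "shared"])
        with pytest.raises(ValueError, match="≥ 2"):
            identity_distribution_tests(pairs)


class TestChromosomeDistribution:
    def _summary(self, chrom, n_genes, intra, inter):
        return ChromosomeSummary(chromosome=chrom, n_genes=n_genes,
                                 n_dup_genes_intra=intra, n_dup_genes_inter=inter,
                                 n_specific_intra=0, n_specific_inter=0)

    def _genome(self, summaries):
        return ChromosomeSummary(
            chromosome="All",
            n_genes=sum(s.n_genes for s in summaries),
            n_dup_genes_intra=sum(s.n_dup_genes_intra for s in summaries),
            n_dup_genes_inter=sum(s.n_dup_genes_inter for s in summaries),
            n_specific_intra=0, n_specific_inter=0,
        )

    def test_uniform_content_not_significant(self):
        summaries = [self._summary(str(i), 1000, 50, 200) for i in range(10)]
        out = chromosome_distribution_test(summaries, self._genome(summaries))
        assert out["heterogeneity"]["p_value"] > 0.05

    def test_single_chromosome_skipped_with_message(self):
        summaries = [self._summary("1", 1000, 50, 200)]
        out = chromosome_distribution_test(summaries, self._genome(summaries))
        assert out["heterogeneity"] is None
        assert "skipped" in out["message"]

    def test_published_counts_heterogeneity_and_enrichment(self):
        models, pairs = build_genome_fixture()
        summaries, genome, table = summarize_by_chromosome(pairs, models)
        out = chromosome_distribution_test(summaries, genome)
        assert out["heterogeneity"]["p_value"] < 0.05
        # flag set == chromosomes whose content exceeds 2x the genome average,
        # recomputed here directly from the published counts
        expected = {
            s.chromosome for s in summaries
            if s.duplicate_content > 2 * genome.duplicate_content
        }
        flagged = set(table.loc[table["enriched"], "chromosome"])
        assert flagged == expected
        # the excess-intra chromosomes include 15, 29 and X
        sig_excess = {
            c for c, row in out["per_chromosome_intra_binomial"].items()
            if row["p_value"] < 0.05 and row["excess_intra"]
        }
        assert {"15", "29", "X"} <= sig_excess

    def test_small_expected_cells_merged_with_warning(self):
        summaries = [self._summary("1", 10000, 500, 2000),
                     self._summary("2", 3, 0, 0),
                     self._summary("3", 9000, 400, 1500)]
        with pytest.warns(UserWarning, match="merging"):
            out = chromosome_distribution_test(summaries, self._genome(summaries))
        assert out["heterogeneity"]["dof"] == 1


def test_benjamini_hochberg_monotone():
    adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.5])
    assert adj == sorted(adj)
    assert all(a >= p for a, p in zip(adj, [0.01, 0.02, 0.04, 0.5]))
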