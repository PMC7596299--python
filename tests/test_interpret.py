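"""Interpretation statistics: enrichment scores, concordance, repartition."""

import numpy as np
import pandas as pd
import pytest

from coexnet import interpret
from coexnet.interpret import AnnotationTable, ExternalClustering
from coexnet.types import ModulePartition


def _partition(labels: dict[str, str], provenance="merged") -> ModulePartition:
    return ModulePartition(assignment=pd.Series(labels), provenance=provenance)


def _partition_with_counts(module_size=50, universe=1000, feature=100, overlap=20):
    """Partition + feature set realizing a given 2x2 contingency table."""
    genes = [f"g{i}" for i in range(universe)]
    labels = ["m1"] * module_size + ["rest"] * (universe - module_size)
    part = _partition(dict(zip(genes, labels)))
    feature_genes = set(genes[:overlap]) | set(
        genes[module_size : module_size + feature - overlap]
    )
    return part, feature_genes


class TestEnrichmentTest:
    def test_exact_expectation_scores_zero(self):
        # feature hits exactly its expected in-module share -> chi2 = 0
        part, _ = _partition_with_counts()
        genes = list(part.assignment.index)
        feature = set(genes[:5]) | set(genes[50:145])  # 5/50 = 95/950 = 10%
        chi2, p, direction = interpret.enrichment_test(part, feature, "m1")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert direction == "none"

    def test_hand_computed_table(self):
        # [[20,30],[80,870]]: chi2 = 52.63, p < 1e-5, enriched
        part, feature = _partition_with_counts(50, 1000, 100, 20)
        chi2, p, direction = interpret.enrichment_test(part, feature, "m1")
        assert chi2 == pytest.approx(52.63, abs=0.005)
        assert p < 1e-5
        assert direction == "enriched"

    def test_complement_flips_direction_same_statistic(self):
        part, feature = _partition_with_counts(50, 1000, 100, 20)
        complement = set(part.assignment.index) - feature
        chi2_f, _, dir_f = interpret.enrichment_test(part, feature, "m1")
        chi2_c, _, dir_c = interpret.enrichment_test(part, complement, "m1")
        assert chi2_f == pytest.approx(chi2_c, abs=1e-9)
        assert {dir_f, dir_c} == {"enriched", "depleted"}

    def test_empty_feature_is_degenerate(self):
        part, _ = _partition_with_counts()
        chi2, p, direction = interpret.enrichment_test(part, set(), "m1")
        assert (chi2, p, direction) == (0.0, 1.0, "none")

    def test_fisher_flag_agrees_on_direction(self):
        part, feature = _partition_with_counts(50, 1000, 100, 20)
        _, p, direction = interpret.enrichment_test(part, feature, "m1", fisher=True)
        assert direction == "enriched" and p < 1e-4


class TestScoreConditions:
    def _table_for(self, overlap):
        part, feature = _partition_with_counts(50, 1000, 100, overlap)
        ann = AnnotationTable(
            features=pd.DataFrame(
                {"f": [g in feature for g in part.assignment.index]},
                index=part.assignment.index,
            )
        )
        return interpret.score_conditions(part, ann)

    def test_strong_enrichment_scores_plus_two(self):
        assert self._table_for(20).scores.loc["m1", "f"] == 2

    def test_weak_enrichment_scores_plus_one(self):
        # overlap 10: chi2 ~ 5.85, 1e-5 < p < 0.05
        score = self._table_for(10)
        p = score.detail.query("module == 'm1'").p_value.iloc[0]
        assert 1e-5 < p < 0.05
        assert score.scores.loc["m1", "f"] == 1

    def test_non_significant_scores_zero(self):
        # overlap 7: p ~ 0.33
        score = self._table_for(7)
        assert score.detail.query("module == 'm1'").p_value.iloc[0] > 0.05
        assert score.scores.loc["m1", "f"] == 0

    def test_condition_score_sums_over_predictors(self):
        part, feature = _partition_with_counts(50, 1000, 100, 20)
        feats = pd.DataFrame(
            {
                "pred_a": [g in feature for g in part.assignment.index],
                "pred_b": [g in feature for g in part.assignment.index],
            },
            index=part.assignment.index,
        )
        ann = AnnotationTable(features=feats, groups={"cond": ["pred_a", "pred_b"]})
        score = interpret.score_conditions(part, ann)
        assert score.scores.loc["m1", "cond"] == 4

    def test_random_features_score_near_zero_on_average(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(1000)]
        labels = rng.choice(["m1", "m2", "m3", "grey"], size=1000)
        part = _partition(dict(zip(genes, labels)))
        feats = pd.DataFrame(
            rng.random((1000, 500)) < 0.1, index=genes,
            columns=[f"f{j}" for j in range(500)],
        )
        score = interpret.score_conditions(part, AnnotationTable(features=feats))
        assert abs(score.detail["score"].mean()) < 0.1


TOY = {
    "g1": ("M1", "C1"),
    "g2": ("M1", "C1"),
    "g3": ("M1", "C2"),
    "g4": ("M2", "C2"),
    "g5": ("M2", "C2"),
    "g6": ("M2", "C3"),
}


def _toy():
    part = _partition({g: m for g, (m, _) in TOY.items()})
    ext = ExternalClustering(labels=pd.Series({g: c for g, (_, c) in TOY.items()}))
    return part, ext


def same_module_oracle(part, ext):
    """Exhaustive pair enumeration of the shared-module statistic."""
    genes = [g for g in part.assignment.index if g in ext.labels.index]
    count = 0
    for g in genes:
        for other in genes:
            if (
                other != g
                and ext.labels[other] == ext.labels[g]
                and part.assignment[other] == part.assignment[g]
            ):
                count += 1
                break
    return count


def plurality_oracle(part, ext):
    """Exhaustive evaluation of the unique-plurality statistic."""
    genes = [g for g in part.assignment.index if g in ext.labels.index]
    count = 0
    for g in genes:
        cluster_genes = [o for o in genes if ext.labels[o] == ext.labels[g]]
        tallies = {}
        for o in cluster_genes:
            tallies[part.assignment[o]] = tallies.get(part.assignment[o], 0) + 1
        best = max(tallies.values())
        winners = [m for m, c in tallies.items() if c == best]
        if len(winners) == 1 and part.assignment[g] == winners[0]:
            count += 1
    return count


class TestConcordance:
    def test_toy_same_module_count(self):
        part, ext = _toy()
        count, frac = interpret.concordance_same_module(part, ext)
        assert count == 4 == same_module_oracle(part, ext)
        assert frac == pytest.approx(4 / 6)

    def test_toy_plurality_count(self):
        part, ext = _toy()
        count, frac = interpret.concordance_plurality(part, ext)
        assert count == 5 == plurality_oracle(part, ext)
        assert frac == pytest.approx(5 / 6)

    def test_identical_partitions_fully_concordant(self):
        genes = [f"g{i}" for i in range(20)]
        labels = [f"m{i % 4}" for i in range(20)]
        part = _partition(dict(zip(genes, labels)))
        ext = ExternalClustering(labels=pd.Series(dict(zip(genes, labels))))
        assert interpret.concordance_same_module(part, ext)[1] == 1.0
        assert interpret.concordance_plurality(part, ext)[1] == 1.0

    def test_singleton_clusters_never_share(self):
        genes = [f"g{i}" for i in range(6)]
        part = _partition(dict(zip(genes, ["m1"] * 6)))
        ext = ExternalClustering(labels=pd.Series(dict(zip(genes, [f"c{i}" for i in range(6)]))))
        assert interpret.concordance_same_module(part, ext)[0] == 0

    def test_even_split_cluster_contributes_zero_to_plurality(self):
        genes = ["a", "b", "c", "d"]
        part = _partition({"a": "m1", "b": "m1", "c": "m2", "d": "m2"})
        ext = ExternalClustering(labels=pd.Series({g: "C" for g in genes}))
        assert interpret.concordance_plurality(part, ext)[0] == 0

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(32)
        genes = [f"g{i}" for i in range(60)]
        part = _partition(dict(zip(genes, rng.choice(list("xyz"), 60))))
        ext = ExternalClustering(labels=pd.Series(dict(zip(genes, rng.choice(list("pqrs"), 60)))))
        base = (
            interpret.concordance_same_module(part, ext)[0],
            interpret.concordance_plurality(part, ext)[0],
        )
        remapped = _partition(
            {g: {"x": "blue", "y": "red", "z": "tan"}[m] for g, m in part.assignment.items()}
        )
        assert base == (
            interpret.concordance_same_module(remapped, ext)[0],
            interpret.concordance_plurality(remapped, ext)[0],
        )

    def test_matches_oracles_on_random_assignments(self):
        rng = np.random.default_rng(33)
        genes = [f"g{i}" for i in range(40)]
        part = _partition(dict(zip(genes, rng.choice(list("abc"), 40))))
        ext = ExternalClustering(labels=pd.Series(dict(zip(genes, rng.choice(list("defg"), 40)))))
        assert interpret.concordance_same_module(part, ext)[0] == same_module_oracle(part, ext)
        assert interpret.concordance_plurality(part, ext)[0] == plurality_oracle(part, ext)

    def test_no_shared_genes_is_an_error(self):
        part = _partition({"a": "m1", "b": "m1"})
        ext = ExternalClustering(labels=pd.Series({"x": "c1"}))
        with pytest.raises(ValueError, match="shared"):
            interpret.concordance_same_module(part, ext)


class TestPreferentialDistribution:
    def test_toy_preferences(self):
        part, ext = _toy()
        table = interpret.preferential_distribution(part, ext)
        assert table.loc["C1", "preferred_module"] == "M1"
        assert table.loc["C2", "preferred_module"] == "M2"
        assert table.loc["C3", "preferred_module"] == "M2"
        counts = table[table.preferential].preferred_module.value_counts()
        assert counts["M1"] == 1 and counts["M2"] == 2

    def test_nested_clusters_all_preferential(self):
        genes = [f"g{i}" for i in range(12)]
        part = _partition(dict(zip(genes, ["m1"] * 6 + ["m2"] * 6)))
        ext = ExternalClustering(
            labels=pd.Series(dict(zip(genes, ["c1"] * 3 + ["c2"] * 3 + ["c3"] * 6)))
        )
        table = interpret.preferential_distribution(part, ext)
        assert table.preferential.all()
        assert table[table.preferential].shape[0] == 3


class TestConcordanceNull:
    def test_same_seed_reproduces_p_values(self):
        part, ext = _toy()
        a = interpret.concordance_null(part, ext, n_perm=99, seed=5)
        b = interpret.concordance_null(part, ext, n_perm=99, seed=5)
        assert a.p_perm_same_module == b.p_perm_same_module
        assert a.p_perm_plurality == b.p_perm_plurality

    def test_strongly_concordant_fixture_reaches_minimum_p(self):
        genes = [f"g{i}" for i in range(120)]
        modules_ = [f"m{i // 4}" for i in range(120)]  # many small modules
        clusters = [f"c{i // 4}" for i in range(120)]  # perfectly aligned
        part = _partition(dict(zip(genes, modules_)))
        ext = ExternalClustering(labels=pd.Series(dict(zip(genes, clusters))))
        report = interpret.concordance_null(part, ext, n_perm=999, seed=6)
        assert report.p_perm_same_module == pytest.approx(1 / 1000)
        assert report.p_chi2_same_module < 1e-10

    def test_null_p_values_roughly_uniform_under_independence(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(35)
        genes = [f"g{i}" for i in range(300)]
        pvals = []
        for _ in range(60):
            part = _partition(dict(zip(genes, rng.choice([f"m{i}" for i in range(10)], 300))))
            ext = ExternalClustering(
                labels=pd.Series(dict(zip(genes, rng.choice([f"c{i}" for i in range(30)], 300))))
            )
            rep = interpret.concordance_null(part, ext, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(rep.p_perm_same_module)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRepartition:
    def _curated(self):
        return pd.DataFrame(
            {
                "pathway": [
                    "photosynthesis", "photosynthesis", "photosynthesis",
                    "tca_cycle", "tca_cycle", "tca_cycle", "tca_cycle",
                    "ribosome", "ribosome", "ribosome",
                ]
            },
            index=[f"g{i}" for i in range(10)],
        )

    def test_single_module_set_has_one_nonzero_column(self):
        genes = [f"g{i}" for i in range(10)]
        part = _partition(dict(zip(genes, ["blue"] * 10)))
        table, missing = interpret.repartition_table(part, self._curated())
        assert list(table.columns) == ["blue"]
        assert missing == []

    def test_matches_hand_cross_tabulation(self):
        genes = [f"g{i}" for i in range(10)]
        labels = ["m1", "m1", "m2", "m2", "m2", "m3", "m1", "m3", "m3", "m3"]
        part = _partition(dict(zip(genes, labels)))
        table, _ = interpret.repartition_table(part, self._curated())
        assert table.loc["photosynthesis", "m1"] == 2
        assert table.loc["photosynthesis", "m2"] == 1
        assert table.loc["tca_cycle", "m2"] == 2
        assert table.loc["ribosome", "m3"] == 3

    def test_row_sums_conserve_category_sizes_and_missing_reported(self):
        genes = [f"g{i}" for i in range(8)]  # g8, g9 missing from partition
        part = _partition(dict(zip(genes, ["m1"] * 4 + ["m2"] * 4)))
        table, missing = interpret.repartition_table(part, self._curated())
        assert missing == ["g8", "g9"]
        assert table.sum(axis=1).to_dict() == {
            "photosynthesis": 3, "tca_cycle": 4, "ribosome": 1
        }
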