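import numpy as np
import pytest
from scipy import stats

from glycove.celltype import (
    cell_type_summary,
    detected_genes,
    merge_clusters,
    parse_cluster_label,
    percent_identified,
    rout_outliers,
    signature_fraction,
    signature_fraction_difference,
    signature_genes,
    surface_detected_fraction,
)
from glycove.io_formats import ClusterExpression


def expr(genes, clusters, values):
    return ClusterExpression(genes=genes, clusters=clusters, values=np.array(values, float))


def rout_oracle(values, q=0.001, max_fraction=0.3):
    """Straightforward implementation of the published ROUT recipe:
    Lorentzian-loss robust location (grid search), RSDR from the 68.27th
    percentile of |residuals| with an N/(N-1) correction, then an FDR scan
    of the largest residuals against t tails with N-1 df."""
    vals = np.asarray(values, float)
    n = len(vals)
    center = float(np.median(vals))
    for _ in range(200):
        scale = np.percentile(np.abs(vals - center), 68.27) * n / (n - 1)
        if scale == 0:
            break
        grid = np.linspace(vals.min(), vals.max(), 4001)
        merit = np.log1p(((vals[None, :] - grid[:, None]) / scale) ** 2).sum(axis=1)
        new = float(grid[merit.argmin()])
        if abs(new - center) < 1e-12:
            break
        center = new
    rsdr = np.percentile(np.abs(vals - center), 68.27) * n / (n - 1)
    res = np.abs(vals - center)
    order = np.argsort(-res, kind="stable")
    flags = np.zeros(n, bool)
    k = 0
    for i in range(max(1, int(np.floor(max_fraction * n)))):
        if rsdr == 0:
            p = 0.0 if res[order[i]] > 0 else 1.0
        else:
            p = 2 * stats.t.sf(res[order[i]] / rsdr, n - 1)
        if p < q * (i + 1) / n:
            k = i + 1
    flags[order[:k]] = True
    return flags, center


class TestMergeClusters:
    def test_consecutive_same_description_collapse_with_max(self):
        e = expr(["g"], ["1 Endo", "2 Endo", "3 Astro"], [[3.0, 7.0, 2.0]])
        merged = merge_clusters(e)
        assert merged.descriptions == ["Endo", "Astro"]
        assert merged.column("Endo")[0] == 7.0
        assert merged.provenance["Endo"] == ["1 Endo", "2 Endo"]

    def test_all_distinct_descriptions_identity_merge(self):
        e = expr(["g"], ["1 A", "2 B", "3 C"], [[1.0, 2.0, 3.0]])
        merged = merge_clusters(e)
        assert merged.descriptions == ["A", "B", "C"]
        np.testing.assert_allclose(merged.values, e.values)

    def test_non_consecutive_repeats_stay_separate(self):
        e = expr(["g"], ["1 A", "2 B", "3 A"], [[1.0, 2.0, 3.0]])
        merged = merge_clusters(e)
        assert len(merged.descriptions) == 3
        assert merged.descriptions[0] == "A" and merged.descriptions[2] == "A #2"

    def test_multi_token_descriptions_split_on_first_whitespace(self):
        e = expr(["g"], ["10 L2-3 IT", "11 L2-3 IT"], [[1.0, 2.0]])
        assert merge_clusters(e).descriptions == ["L2-3 IT"]
        assert parse_cluster_label("388 Micro-PVM") == ("388", "Micro-PVM")

    def test_unparsable_label_error_names_label(self):
        e = expr(["g"], ["Endo only"], [[1.0]])
        with pytest.raises(ValueError, match="Endo only"):
            merge_clusters(e)

    def test_idempotent_and_max_preserving(self):
        rng = np.random.default_rng(4)
        labels = [f"{i + 1} {d}" for i, d in enumerate("AABBBCADD")]
        values = rng.random((6, 9)) * (rng.random((6, 9)) > 0.3)
        e = expr([f"g{i}" for i in range(6)], labels, values)
        merged = merge_clusters(e)
        # re-merge the already merged matrix (labels re-numbered, suffixes stripped)
        relabeled = ClusterExpression(
            genes=merged.genes,
            clusters=[f"{j + 1} {d.split(' #')[0]}x{j}" for j, d in enumerate(merged.descriptions)],
            values=merged.values,
        )
        np.testing.assert_allclose(merge_clusters(relabeled).values, merged.values)
        np.testing.assert_allclose(
            merged.values.max(axis=1), e.values.max(axis=1)
        )


class TestDetection:
    def setup_method(self):
        self.merged = merge_clusters(
            expr(["g1", "g2", "g3"], ["1 Endo", "2 Astro"],
                 [[0.0, 1.0], [0.3, 0.0], [2.0, 2.0]])
        )

    def test_strictly_positive_detection(self):
        assert detected_genes(self.merged, "Endo") == {"g2", "g3"}
        assert detected_genes(self.merged, "Astro") == {"g1", "g3"}

    def test_threshold_at_max_empties_the_set(self):
        assert detected_genes(self.merged, "Endo", threshold=2.0) == set()

    def test_unknown_cluster_is_an_error(self):
        with pytest.raises(KeyError, match="VLMC"):
            detected_genes(self.merged, "VLMC")


class TestPercentIdentified:
    def test_ratio_and_edge_cases(self):
        merged = merge_clusters(
            expr(["a", "b", "c", "d", "e"], ["1 Endo", "2 Astro"],
                 [[1, 0], [1, 0], [1, 1], [1, 0], [0, 0]])
        )
        surface = {"a", "b", "c", "d"}
        out = percent_identified(merged, surface, identified={"a", "b"})
        assert out["Endo"] == 50.0
        assert out["Astro"] == 0.0  # only c detected, not identified
        assert percent_identified(merged, surface, identified=surface)["Endo"] == 100.0

    def test_cluster_without_detected_surface_genes_is_undefined(self):
        merged = merge_clusters(
            expr(["a", "b"], ["1 Endo", "2 Astro"], [[1, 0], [1, 0]])
        )
        out = percent_identified(merged, {"a", "b"}, {"a"})
        assert np.isnan(out["Astro"])


class TestROUT:
    def test_identical_values_give_no_outliers_and_zero_rsdr(self):
        res = rout_outliers([5.0] * 10)
        assert not res.outlier_flags.any() and res.rsdr == 0.0

    def test_planted_high_outlier_recovered(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(10, 1, 74), [10 + 20.0]])
        res = rout_outliers(vals, q=0.001)
        assert list(np.flatnonzero(res.outlier_flags)) == [74]
        assert res.directions[74] == "high"

    def test_low_outlier_direction(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([[-25.0], rng.normal(0, 1, 74)])
        res = rout_outliers(vals, q=0.001)
        assert res.directions.get(0) == "low"

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            rout_outliers([1.0, 2.0, 3.0])

    def test_flags_monotone_in_q(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 70), rng.normal(6, 1, 5)])
        n_small = rout_outliers(vals, q=1e-6).outlier_flags.sum()
        n_big = rout_outliers(vals, q=0.01).outlier_flags.sum()
        assert n_small <= n_big

    def test_matches_independent_recipe_implementation(self):
        rng = np.random.default_rng(3)
        for k_out in (0, 1, 3):
            vals = np.concatenate(
                [rng.normal(50, 2, 75 - k_out), 50 + rng.choice([-1, 1], k_out) * rng.uniform(15, 30, k_out)]
            )
            res = rout_outliers(vals, q=0.01)
            oracle_flags, oracle_center = rout_oracle(vals, q=0.01)
            assert np.array_equal(res.outlier_flags, oracle_flags)
            assert res.robust_center == pytest.approx(oracle_center, abs=0.05)


class TestSignatures:
    def setup_method(self):
        self.merged = merge_clusters(
            expr(
                ["a", "b", "c", "d", "n"],
                ["1 Endo", "2 VLMC", "3 Oligo"],
                [[1, 0, 0], [2, 0, 0], [0, 1, 0], [0, 0, 3], [0, 0, 0]],
            )
        )

    def test_genes_detected_in_exactly_one_cluster(self):
        sigs = signature_genes(self.merged)
        assert sigs == {"a": "Endo", "b": "Endo", "c": "VLMC", "d": "Oligo"}

    def test_multi_cluster_and_undetected_genes_excluded(self):
        merged = merge_clusters(
            expr(["x", "y"], ["1 Endo", "2 VLMC"], [[1, 1], [0, 0]])
        )
        assert signature_genes(merged) == {}

    def test_signature_sets_disjoint_across_clusters(self):
        rng = np.random.default_rng(5)
        vals = (rng.random((40, 4)) > 0.5).astype(float)
        merged = merge_clusters(
            expr([f"g{i}" for i in range(40)], [f"{j} T{j}" for j in range(1, 5)], vals)
        )
        sigs = signature_genes(merged)
        by_cluster = {}
        for g, c in sigs.items():
            by_cluster.setdefault(c, set()).add(g)
        sets = list(by_cluster.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_fraction_examples(self):
        sigs = {"a": "Endo", "b": "Endo", "c": "VLMC", "d": "Oligo"}
        out = signature_fraction(sigs, identified={"a", "b", "c", "d"})
        assert out == {"Endo": 50.0, "VLMC": 25.0, "Oligo": 25.0}
        single = signature_fraction(sigs, identified={"c"})
        assert single["VLMC"] == 100.0 and single["Endo"] == 0.0

    def test_identical_datasets_give_zero_difference(self):
        sigs = {"a": "Endo", "b": "VLMC"}
        diff = signature_fraction_difference(sigs, {"a", "b"}, {"a", "b"})
        assert all(v == 0.0 for v in diff.values())

    def test_no_identified_signature_genes_warns(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = signature_fraction({"a": "Endo"}, identified=set())
        assert np.isnan(out["Endo"])


class TestSurfaceFractionAndSummary:
    def test_surface_detected_fraction(self):
        merged = merge_clusters(
            expr(
                [f"g{i}" for i in range(10)],
                ["1 Endo"],
                [[1.0]] * 10,
            )
        )
        out = surface_detected_fraction(merged, {"g0", "g1"})
        assert out["Endo"] == 20.0
        assert surface_detected_fraction(merged, set())["Endo"] == 0.0
        assert surface_detected_fraction(merged, {f"g{i}" for i in range(10)})["Endo"] == 100.0

    def test_summary_flags_planted_cluster_and_skips_undefined(self):
        rng = np.random.default_rng(6)
        n_genes, n_types = 400, 10
        vals = (rng.random((n_genes, n_types)) > 0.4).astype(float)
        vals[:, 9] = 0.0  # no detected genes: percent undefined there
        genes = [f"g{i}" for i in range(n_genes)]
        labels = [f"{j + 1} T{j + 1}" for j in range(n_types)]
        merged = merge_clusters(expr(genes, labels, vals))
        surface = set(genes)
        # identify half the genes overall but nearly all of cluster T1
        identified = {g for g in genes if rng.random() < 0.3}
        identified |= {g for g, v in zip(genes, vals[:, 0]) if v > 0}
        df = cell_type_summary(merged, surface, identified, q=0.01)
        assert df.loc[df["cluster"] == "T1", "outlier_flag"].item()
        assert df.loc[df["cluster"] == "T1", "direction"].item() == "high"
        t10 = df[df["cluster"] == "T10"]
        assert np.isnan(t10["percent"].item()) and not t10["outlier_flag"].item()
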