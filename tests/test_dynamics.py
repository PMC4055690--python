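import math

import numpy as np
import pandas as pd
import pytest

from ampdyn.beta import distance_matrix
from ampdyn.dynamics import (
    compare_slopes,
    cumulative_richness,
    detect_core,
    fit_power_law,
    mean_w,
    moving_window,
    run_region_comparison,
    shared_core,
    shared_core_summary,
    similarity_decay,
    taxa_time_relationship,
)
from ampdyn.io_formats import CommunityTable, DistanceMatrix, TimeSeriesDesign


def design_for(region_samples):
    """region_samples: {region: [(sample_id, t, r), ...]}"""
    rows = []
    for region, triples in region_samples.items():
        for sid, t, r in triples:
            rows.append({"sample_id": sid, "time_point": t, "replicate": r, "region": region})
    return TimeSeriesDesign(pd.DataFrame(rows).set_index("sample_id"))


def single_replicate_design(T, region="V4"):
    return design_for({region: [(f"s{t}", t, 1) for t in range(1, T + 1)]})


class TestDetectCore:
    def _fixture(self):
        # taxon A present always; B misses t=2 in both replicates; C misses in one
        counts = np.array(
            [
                [5, 5, 5, 5, 5, 5],  # A
                [3, 3, 0, 0, 1, 1],  # B
                [2, 2, 4, 0, 2, 2],  # C
            ]
        )
        samples = [f"s{t}_{r}" for t in (1, 2, 3) for r in (1, 2)]
        table = CommunityTable(["A", "B", "C"], samples, counts)
        design = design_for({"V4": [(f"s{t}_{r}", t, r) for t in (1, 2, 3) for r in (1, 2)]})
        return table, design

    def test_always_present_taxon_in_core(self):
        table, design = self._fixture()
        core = detect_core(table, design, "V4")
        assert "A" in core.taxon_ids

    def test_single_gap_excludes_with_occupancy(self):
        table, design = self._fixture()
        core = detect_core(table, design, "V4")
        assert "B" not in core.taxon_ids
        assert core.occupancy["B"] == 2

    def test_pooled_vs_strict_replicate_reading(self):
        table, design = self._fixture()
        pooled = detect_core(table, design, "V4")
        strict = detect_core(table, design, "V4", pool_replicates=False)
        assert "C" in pooled.taxon_ids  # seen in one replicate at t=2
        assert "C" not in strict.taxon_ids

    def test_threshold_monotonicity(self):
        table, design = self._fixture()
        sizes = [
            len(detect_core(table, design, "V4", min_occupancy=k).taxon_ids)
            for k in (1, 2, 3)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_abundance_share_in_unit_interval(self):
        table, design = self._fixture()
        core = detect_core(table, design, "V4")
        assert 0.0 < core.abundance_share <= 1.0

    def test_planted_core_recovered(self, default_experiment):
        exp = default_experiment
        params = exp.params
        core = detect_core(exp.tables["V4"], exp.design, "V4")
        true_min_rel = exp.true_series.abundances[: params.n_core].min(axis=1)
        for i, taxon in enumerate(exp.true_series.core_ids):
            if true_min_rel[i] >= 0.005:
                assert taxon in core.taxon_ids


class TestSharedCore:
    def _taxonomy(self):
        return pd.DataFrame(
            {
                "phylum": ["P1", "P1", "P2", "P2"],
                "order": ["O1", "O2", "O1", "O3"],
            },
            index=pd.Index(["A", "B", "C", "D"], name="taxon_id"),
        )

    def _tables(self, counts_a, counts_b):
        taxa = ["A", "B", "C", "D"]
        samples_a = ["a1", "a2"]
        samples_b = ["b1", "b2"]
        ta = CommunityTable(taxa, samples_a, counts_a)
        tb = CommunityTable(taxa, samples_b, counts_b)
        design = design_for(
            {"V1V3": [("a1", 1, 1), ("a2", 2, 1)], "V4": [("b1", 1, 1), ("b2", 2, 1)]}
        )
        return ta, tb, design

    def test_shared_orders_and_shares(self):
        # region A core {A(O1):60, B(O2):40}; region B core {C(O1):30, D(O3):70}
        counts_a = np.array([[60, 60], [40, 40], [0, 0], [0, 0]])
        counts_b = np.array([[0, 0], [0, 0], [30, 30], [70, 70]])
        ta, tb, design = self._tables(counts_a, counts_b)
        core_a = detect_core(ta, design, "V1V3")
        core_b = detect_core(tb, design, "V4")
        shared = shared_core(core_a, core_b, self._taxonomy(), ta, tb, design)
        assert list(shared.index[shared["shared"]]) == ["O1"]
        shares = shared_core_summary(shared)
        assert shares["share_V1V3"] == pytest.approx(0.6)
        assert shares["share_V4"] == pytest.approx(0.3)

    def test_identical_cores_fully_shared(self):
        counts = np.array([[60, 60], [40, 40], [0, 0], [0, 0]])
        ta, tb, design = self._tables(counts, counts)
        core_a = detect_core(ta, design, "V1V3")
        core_b = detect_core(tb, design, "V4")
        shared = shared_core(core_a, core_b, self._taxonomy(), ta, tb, design)
        shares = shared_core_summary(shared)
        assert shares["share_V1V3"] == pytest.approx(1.0)
        assert shares["share_V4"] == pytest.approx(1.0)

    def test_unclassified_taxa_grouped_by_parent(self):
        taxonomy = pd.DataFrame(
            {"phylum": ["P9"], "order": [None]},
            index=pd.Index(["A"], name="taxon_id"),
        )
        counts = np.array([[10, 10], [0, 0], [0, 0], [0, 0]])
        ta, tb, design = self._tables(counts, counts)
        core_a = detect_core(ta, design, "V1V3")
        core_b = detect_core(tb, design, "V4")
        shared = shared_core(core_a, core_b, taxonomy, ta, tb, design)
        assert "unclassified_P9" in shared.index


class TestMovingWindow:
    def test_constant_community_is_zero(self):
        values = np.zeros((6, 6))
        D = DistanceMatrix([f"s{t}_{r}" for t in (1, 2, 3) for r in (1, 2)], values)
        design = design_for({"V4": [(f"s{t}_{r}", t, r) for t in (1, 2, 3) for r in (1, 2)]})
        mw = moving_window(D, design, "V4")
        assert np.allclose(mw.means, 0.0)

    def test_single_pair_case(self):
        values = np.array([[0.0, 0.6], [0.6, 0.0]])
        D = DistanceMatrix(["s1", "s2"], values)
        design = design_for({"V4": [("s1", 1, 1), ("s2", 2, 1)]})
        mw = moving_window(D, design, "V4")
        assert mw.means.tolist() == [pytest.approx(0.6)]
        assert mw.sems.tolist() == [0.0]
        assert mw.single_pair

    def test_two_replicates_average_four_pairings(self):
        ids = ["s1_1", "s1_2", "s2_1", "s2_2"]
        values = np.zeros((4, 4))
        # distances between t1 and t2 samples: 0.1, 0.2, 0.3, 0.4
        pairs = {(0, 2): 0.1, (0, 3): 0.2, (1, 2): 0.3, (1, 3): 0.4}
        for (i, j), v in pairs.items():
            values[i, j] = values[j, i] = v
        D = DistanceMatrix(ids, values)
        design = design_for({"V4": [("s1_1", 1, 1), ("s1_2", 1, 2), ("s2_1", 2, 1), ("s2_2", 2, 2)]})
        mw = moving_window(D, design, "V4")
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        assert mw.means[0] == pytest.approx(vals.mean())
        assert mw.sems[0] == pytest.approx(vals.std(ddof=1) / 2.0)


class TestSimilarityDecay:
    def _matrix_from_similarity(self, T, sim_of_lag):
        ids = [f"s{t}" for t in range(1, T + 1)]
        values = np.zeros((T, T))
        for i in range(T):
            for j in range(T):
                if i != j:
                    values[i, j] = 1.0 - sim_of_lag(abs(i - j))
        return DistanceMatrix(ids, values)

    def test_exact_log_linear_input(self):
        D = self._matrix_from_similarity(8, lambda dt: 10 ** (-0.02 * dt))
        fits = similarity_decay(D, single_replicate_design(8), "V4")
        assert len(fits) == 1
        assert fits[0].slope == pytest.approx(-0.02, abs=1e-12)
        assert fits[0].r2 == pytest.approx(1.0)

    def test_flat_similarity(self):
        D = self._matrix_from_similarity(6, lambda dt: 0.5)
        fit = similarity_decay(D, single_replicate_design(6), "V4")[0]
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.p_slope > 0.9

    def test_nonpositive_similarities_excluded(self):
        D = self._matrix_from_similarity(8, lambda dt: 0.8 if dt < 4 else 0.0)
        fit = similarity_decay(D, single_replicate_design(8), "V4")[0]
        assert fit.n_excluded > 0
        assert fit.n_pairs + fit.n_excluded == 8 * 7 // 2

    def test_recovers_latent_slope_from_noisy_observations(self):
        """Mean recovered slope over repeated noisy samplings stays within
        two standard errors of the slope fitted on the latent similarities."""
        from ampdyn.synthetic import SyntheticParams, generate_true_series, sample_reads
        from ampdyn.beta import bray_curtis

        slopes, stderrs = [], []
        latent_slopes = []
        for seed in range(40):
            params = SyntheticParams(seed=seed)
            series = generate_true_series(params)
            D_lat = self._matrix_from_similarity(
                params.T,
                lambda dt: 1.0,  # placeholder, replaced below
            )
            lat = np.zeros((params.T, params.T))
            for i in range(params.T):
                for j in range(params.T):
                    if i != j:
                        lat[i, j] = bray_curtis(
                            series.abundances[:, i], series.abundances[:, j]
                        )
            D_lat = DistanceMatrix([f"s{t}" for t in range(1, params.T + 1)], lat)
            latent_slopes.append(
                similarity_decay(D_lat, single_replicate_design(params.T), "V4")[0].slope
            )
            table, design = sample_reads(series, params.depth, params.R, seed=seed, region="V4",
                                         replicate_sigma=params.replicate_sigma)
            D_obs = distance_matrix(table, "bray_curtis")
            for fit in similarity_decay(D_obs, design, "V4"):
                slopes.append(fit.slope)
                stderrs.append(fit.stderr_slope)
        mean_obs = np.mean(slopes)
        mean_lat = np.mean(latent_slopes)
        assert abs(mean_obs - mean_lat) < 2 * np.mean(stderrs)


class TestCompareSlopes:
    def test_hand_computed_pooled_t(self):
        res = compare_slopes([-1.0, -3.0], [-2.0, -4.0])
        assert res.t == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(0.5528, abs=1e-3)

    def test_identical_groups(self):
        res = compare_slopes([-1.0, -2.0], [-1.0, -2.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_zero_variance_cases(self):
        equal = compare_slopes([1.0, 1.0], [1.0, 1.0])
        assert equal.p == 1.0 and equal.degenerate
        shifted = compare_slopes([1.0, 1.0], [2.0, 2.0])
        assert shifted.degenerate and shifted.p == 0.0

    def test_duplicate_design_df(self):
        assert compare_slopes([-1.0, -1.1], [-0.9, -1.2]).df == 2


class TestTaxaTime:
    def test_exact_power_law(self):
        S = 10.0 * np.arange(1, 13) ** 0.5
        c, w, se, r2 = fit_power_law(S)
        assert w == pytest.approx(0.5, abs=1e-12)
        assert c == pytest.approx(10.0, rel=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_constant_community_zero_turnover(self):
        counts = np.tile(np.array([[4], [6]]), (1, 5))
        table = CommunityTable(["A", "B"], [f"s{t}" for t in range(1, 6)], counts)
        fits = taxa_time_relationship(table, single_replicate_design(5), "V4")
        assert fits[0].w == pytest.approx(0.0, abs=1e-12)

    def test_singletons_removed(self):
        counts = np.array([[2, 2, 2], [0, 1, 0], [0, 3, 3]])
        table = CommunityTable(["A", "B", "C"], ["s1", "s2", "s3"], counts)
        S = cumulative_richness(table, single_replicate_design(3), "V4", 1)
        assert S.tolist() == [1, 2, 2]  # B is a whole-series singleton

    def test_invariance_to_relabeling_and_scaling(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(10, 6))
        counts[0] += 2
        table = CommunityTable([f"t{i}" for i in range(10)], [f"s{t}" for t in range(1, 7)], counts)
        design = single_replicate_design(6)
        w0 = taxa_time_relationship(table, design, "V4")[0].w
        perm = rng.permutation(10)
        shuffled = CommunityTable([f"t{i}" for i in perm], table.sample_ids, counts[perm])
        assert taxa_time_relationship(shuffled, design, "V4")[0].w == pytest.approx(w0)
        scaled = CommunityTable(table.taxon_ids, table.sample_ids, counts * 3)
        assert taxa_time_relationship(scaled, design, "V4")[0].w == pytest.approx(w0)

    def test_genus_level_aggregation(self):
        counts = np.array([[2, 0, 0], [0, 3, 0], [0, 0, 4]])
        table = CommunityTable(["A", "B", "C"], ["s1", "s2", "s3"], counts)
        taxonomy = pd.DataFrame(
            {"genus": ["G1", "G1", "G2"]},
            index=pd.Index(["A", "B", "C"], name="taxon_id"),
        )
        S = cumulative_richness(
            table, single_replicate_design(3), "V4", 1, level="genus", taxonomy=taxonomy
        )
        assert S.tolist() == [1, 1, 2]

    def test_mean_w_over_replicates(self, default_experiment):
        exp = default_experiment
        fits = taxa_time_relationship(exp.tables["V4"], exp.design, "V4")
        assert len(fits) == 2
        w, sem = mean_w(fits)
        assert 0.0 < w < 1.0
        assert sem >= 0.0


class TestRegionComparison:
    def test_self_comparison_is_perfect(self, small_experiment):
        exp = small_experiment
        table = exp.tables["V4"]
        # present the same table as both regions
        frames = exp.design.frame.copy()
        mirrored = table.counts.copy()
        ids_a = [s.replace("V4", "V1V3") for s in table.sample_ids]
        table_a = CommunityTable(table.taxon_ids, ids_a, mirrored)
        rows = []
        for sid in table.sample_ids:
            t = int(exp.design.frame.loc[sid, "time_point"])
            r = int(exp.design.frame.loc[sid, "replicate"])
            rows.append({"sample_id": sid, "time_point": t, "replicate": r, "region": "V4"})
            rows.append({"sample_id": sid.replace("V4", "V1V3"), "time_point": t,
                         "replicate": r, "region": "V1V3"})
        design = TimeSeriesDesign(pd.DataFrame(rows).set_index("sample_id"))
        report = run_region_comparison(
            table_a, table, exp.tree, design, regions=("V1V3", "V4"),
            n_perm=19, nmds_starts=2, seed=0,
        )
        assert report.mantel["bray_curtis"].r == pytest.approx(1.0)
        assert report.moving_window_r["bray_curtis"] == pytest.approx(1.0)
        assert report.slope_tests["bray_curtis"].p == 1.0
        assert report.procrustes.correlation > 0.99

    def test_report_serializes(self, small_experiment):
        exp = small_experiment
        report = run_region_comparison(
            exp.tables["V1V3"], exp.tables["V4"], exp.tree, exp.design,
            n_perm=19, nmds_starts=2, seed=0,
        )
        out = report.to_dict()
        assert set(out["mantel"]) == {"bray_curtis", "unifrac_unweighted", "unifrac_weighted"}
        assert "str_w" in out and "core" in out
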