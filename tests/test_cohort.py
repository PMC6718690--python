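"""PDL1 cohorts and positivity, gene signatures, BH-FDR, survival
stratification and phenotyping robustness checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tamspatial as ts
from tamspatial.errors import DataError

from conftest import make_cells


def _pdl1_cells(values_by_patient, phenotypes=None):
    frames = []
    for pid, vals in values_by_patient.items():
        f = make_cells(np.zeros(len(vals)), np.zeros(len(vals)), PDL1=vals)
        f["patient_id"] = pid
        f["cell_id"] = [f"{pid}_c{i}" for i in range(len(vals))]
        if phenotypes is not None:
            f["phenotype"] = phenotypes[pid]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestPdl1Cohorts:
    def test_cohort_size_and_determinism(self):
        cells = _pdl1_cells({f"P{i}": np.arange(200.0) for i in range(3)})
        a = ts.build_pdl1_cohorts(cells, n_per_patient=100, n_cohorts=2, seed=5)
        b = ts.build_pdl1_cohorts(cells, n_per_patient=100, n_cohorts=2, seed=5)
        assert all(len(c) == 300 for c in a)
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca, cb)

    def test_short_patient_resampled_with_flag(self):
        cells = _pdl1_cells({"P0": np.arange(50.0)})
        (c,) = ts.build_pdl1_cohorts(cells, n_per_patient=100, n_cohorts=1, seed=0)
        assert len(c) == 100 and c["resampled"].all()

    def test_expected_overlap_between_cohorts(self):
        """Two without-replacement draws of n from N cells share ~n²/N."""
        N, n = 400, 100
        cells = _pdl1_cells({"P0": np.arange(float(N))})
        overlaps = []
        for seed in range(40):
            a, b = ts.build_pdl1_cohorts(cells, n_per_patient=n, n_cohorts=2, seed=seed)
            overlaps.append(len(set(a["cell_id"]) & set(b["cell_id"])))
        assert np.mean(overlaps) == pytest.approx(n * n / N, rel=0.2)


class TestPdl1Positivity:
    def test_mean_threshold_example(self):
        cells = _pdl1_cells({"P0": [0.0, 1.0, 2.0, 3.0]})
        thr, flags, frac = ts.pdl1_positivity(cells)
        assert thr == 1.5
        assert list(cells.loc[flags, "PDL1"]) == [2.0, 3.0]
        assert frac == 0.5

    def test_all_equal_gives_zero_fraction(self):
        cells = _pdl1_cells({"P0": [2.0] * 10})
        _, _, frac = ts.pdl1_positivity(cells)
        assert frac == 0.0

    def test_right_skewed_distribution_below_half(self):
        rng = np.random.default_rng(0)
        cells = _pdl1_cells({"P0": rng.lognormal(0, 1, 5000)})
        _, _, frac = ts.pdl1_positivity(cells)
        assert frac < 0.5

    def test_affine_shift_moves_threshold_with_mean(self):
        cells = _pdl1_cells({"P0": [0.0, 1.0, 2.0, 3.0]})
        thr, flags, frac = ts.pdl1_positivity(cells)
        shifted = cells.copy()
        shifted["PDL1"] += 10.0
        thr2, flags2, frac2 = ts.pdl1_positivity(shifted)
        assert thr2 == thr + 10.0
        assert frac2 == frac
        assert (flags2 == flags).all()


class TestPdl1TopPercent:
    def test_flag_count_bounded(self):
        rng = np.random.default_rng(1)
        cells = _pdl1_cells({"P0": rng.uniform(0, 1, 200)})
        flags = ts.pdl1_top_percent(cells, 1.0)
        assert flags.sum() <= 2

    def test_percent_out_of_range_rejected(self):
        cells = _pdl1_cells({"P0": [1.0]})
        for bad in (0.0, 100.0, -5.0):
            with pytest.raises(DataError):
                ts.pdl1_top_percent(cells, bad)

    def test_tumor_only_flag_does_not_make_patient_high(self):
        """The PDL1-high call requires a flagged macrophage; a flagged tumor
        cell alone does not qualify."""
        cells = _pdl1_cells(
            {"P0": [100.0, 1.0, 1.0], "P1": [1.0, 1.0, 90.0]},
            phenotypes={"P0": ["Tumor", "CD68+", "CD68+"], "P1": ["Tumor", "Other", "CD68+"]},
        )
        flags = ts.pdl1_top_percent(cells, 34.0)
        out = ts.classify_pdl1_high_patients(cells, flags).set_index("patient_id")
        assert not out.loc["P0", "pdl1_high"]
        assert out.loc["P1", "pdl1_high"]

    def test_elevated_population_is_modal_top_performer(self, labelled_cells):
        """The population generated with the highest PDL1 location should be
        the most frequent per-patient top performer."""
        (cohort,) = ts.build_pdl1_cohorts(labelled_cells, n_per_patient=1500, n_cohorts=1, seed=2)
        flags = ts.pdl1_top_percent(cohort, 1.0)
        out = ts.classify_pdl1_high_patients(cohort, flags)
        assert out["top_tam_population"].mode().iloc[0] == "CD68+CD206+"


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            ts.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert ts.bh_fdr([0.3])[0] == 0.3

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(ts.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            ts.bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_independent_step_up_and_is_monotone(self, ps):
        """Adjusted values equal the direct step-up formula
        min_k>=i (p_(k) m / k) and preserve the ordering of raw p."""
        adj = ts.bh_fdr(ps)
        p = np.asarray(ps)
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
        for i, j in itertools.combinations(range(m), 2):
            if p[i] <= p[j]:
                assert adj[i] <= adj[j] + 1e-12


class TestSpearmanExactP:
    def test_exact_small_n_matches_enumeration(self):
        """For n <= 9 the p-value is the exact permutation tail, checked
        against a brute-force enumeration."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = ts.spearman_with_p(x, y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_constant_vector_is_missing(self):
        rho, p = ts.spearman_with_p(np.ones(10), np.arange(10))
        assert np.isnan(rho) and np.isnan(p)


class TestEnvironmentalSignature:
    def test_zero_noise_linked_gene_in_refined_set(self):
        # 12 patients so a perfect correlation clears the p < 0.001 cut
        rng = np.random.default_rng(0)
        dens_tbl = pd.DataFrame(
            {
                "patient_id": [f"P{i:03d}" for i in range(12)],
                "roi": "core",
                "compartment": "all",
                "population": "CD68+IRF8+",
                "density": rng.uniform(10, 100, 12),
            }
        )
        cfg = ts.SimulationConfig(
            n_patients=12, seed=0,
            expression=ts.ExpressionParams(
                n_genes=10, n_linked_per_population=3,
                linked_populations=("CD68+IRF8+",), noise_scale=0.0,
            ),
        )
        expr, link = ts.generate_expression(dens_tbl, cfg)
        res = ts.environmental_signature(dens_tbl, expr, "CD68+IRF8+")
        linked = set(link[link["population"] == "CD68+IRF8+"]["gene"])
        assert linked <= set(res.refined_genes)
        sub = res.table.set_index("gene").loc[sorted(linked)]
        np.testing.assert_allclose(sub["rho"], 1.0)

    def test_refined_subset_of_signature_and_fdr_dominates_p(self, density_all):
        cfg = ts.SimulationConfig(n_patients=6, seed=1)
        expr, _ = ts.generate_expression(density_all, cfg)
        res = ts.environmental_signature(density_all, expr, "CD68++CD163+")
        t = res.table.dropna(subset=["p"])
        assert set(res.refined_genes) <= set(res.signature_genes)
        assert (t["fdr"] >= t["p"] - 1e-12).all()

    def test_constant_gene_reported_missing(self, density_all):
        cfg = ts.SimulationConfig(
            n_patients=6, seed=0,
            expression=ts.ExpressionParams(n_genes=5, n_linked_per_population=0, linked_populations=()),
        )
        expr, _ = ts.generate_expression(density_all, cfg)
        expr.iloc[0] = 3.0
        res = ts.environmental_signature(density_all, expr, "CD68+")
        row = res.table.iloc[0]
        assert np.isnan(row["rho"]) and not row["in_signature"]

    def test_too_few_matched_samples_rejected(self, density_all):
        cfg = ts.SimulationConfig(n_patients=6, seed=0)
        expr, _ = ts.generate_expression(density_all, cfg)
        with pytest.raises(DataError):
            ts.environmental_signature(
                density_all, expr[expr.columns[:3]], "CD68+"
            )


class TestSignatureScore:
    def test_single_gene_grouping_equals_median_split(self, density_all):
        cfg = ts.SimulationConfig(n_patients=6, seed=2)
        expr, _ = ts.generate_expression(density_all, cfg)
        g = expr.index[0]
        score, groups = ts.signature_score_and_split(expr, [g])
        direct = expr.loc[g] > expr.loc[g].median()
        assert ((groups == "high") == direct).all()

    def test_affine_rescaling_invariance(self, density_all):
        cfg = ts.SimulationConfig(n_patients=6, seed=2)
        expr, link = ts.generate_expression(density_all, cfg)
        genes = list(expr.index[:20])
        _, g1 = ts.signature_score_and_split(expr, genes)
        expr2 = expr.copy()
        expr2.loc[genes[0]] = expr2.loc[genes[0]] * 7.0 + 3.0
        _, g2 = ts.signature_score_and_split(expr2, genes)
        assert (g1 == g2).all()

    def test_missing_genes_rejected(self, density_all):
        cfg = ts.SimulationConfig(n_patients=6, seed=2)
        expr, _ = ts.generate_expression(density_all, cfg)
        with pytest.raises(DataError):
            ts.signature_score_and_split(expr, ["nope"])

    def test_cluster_samples_deterministic_two_groups(self, density_all):
        cfg = ts.SimulationConfig(n_patients=6, seed=2)
        expr, link = ts.generate_expression(density_all, cfg)
        genes = link[link["population"] == "CD68++CD163+"]["gene"].tolist()
        c1 = ts.cluster_samples(expr, genes, k=2)
        c2 = ts.cluster_samples(expr, genes, k=2)
        assert (c1 == c2).all() and c1.nunique() == 2


class TestTercileStratify:
    def test_one_to_nine(self):
        v = pd.Series(np.arange(1.0, 10.0), index=[f"P{i}" for i in range(9)])
        t = ts.tercile_stratify(v)
        assert list(v[t == "lower"]) == [1, 2, 3]
        assert list(v[t == "middle"]) == [4, 5, 6]
        assert list(v[t == "upper"]) == [7, 8, 9]

    def test_all_equal_upper_empty_with_warning(self):
        v = pd.Series([2.0] * 6)
        with pytest.warns(UserWarning, match="upper"):
            t = ts.tercile_stratify(v)
        assert (t == "upper").sum() == 0

    def test_partition_and_equal_sizes(self):
        rng = np.random.default_rng(3)
        v = pd.Series(rng.permutation(12).astype(float))
        t = ts.tercile_stratify(v)
        assert len(t) == 12
        assert (t.value_counts() == 4).all()


class TestKmLogrank:
    def _records(self, times, events, pids=None):
        pids = pids or [f"P{i}" for i in range(len(times))]
        return pd.DataFrame({"patient_id": pids, "time": times, "event": events})

    def test_identical_groups_give_null_result(self):
        rec = self._records([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=rec["patient_id"])
        curves, chi2, p = ts.km_logrank(rec, groups, ("a", "b"))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        pd.testing.assert_frame_equal(curves["a"], curves["b"])

    def test_six_subject_hand_oracle(self):
        """Frozen observed/expected table: O_A = 2, E_A = 1.4, V = 0.74,
        chi2 = 0.36/0.74."""
        rec = self._records([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 1])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=rec["patient_id"])
        _, chi2, p = ts.km_logrank(rec, groups, ("a", "b"))
        assert chi2 == pytest.approx(0.36 / 0.74, abs=1e-9)
        assert p == pytest.approx(1 - stats.chi2.cdf(0.36 / 0.74, 1), abs=1e-9)

    def test_empty_group_rejected(self):
        rec = self._records([1, 2], [1, 1])
        groups = pd.Series(["a", "a"], index=rec["patient_id"])
        with pytest.raises(DataError):
            ts.km_logrank(rec, groups, ("a", "b"))

    def test_time_rescaling_invariance(self):
        rec = self._records([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 1])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=rec["patient_id"])
        _, chi2, _ = ts.km_logrank(rec, groups, ("a", "b"))
        rec2 = rec.assign(time=rec["time"] * 12.0)
        _, chi2b, _ = ts.km_logrank(rec2, groups, ("a", "b"))
        assert chi2b == pytest.approx(chi2, abs=1e-12)


class TestSubsampleStability:
    def test_full_population_draw_gives_r_one(self, labelled_cells):
        sub = labelled_cells[labelled_cells["phenotype"] == "CD68+IRF8+"]
        res = ts.subsample_stability(
            labelled_cells, "CD68+IRF8+", n_draws=5, n_cells=len(sub), seed=0
        )
        np.testing.assert_allclose(res["r"], 1.0, atol=1e-12)

    def test_jittered_population_highly_stable(self):
        rng = np.random.default_rng(4)
        n = 500
        cells = make_cells(np.zeros(n), np.zeros(n), phenotype=["CD68+"] * n)
        for m in ts.MARKERS:
            base = {"CD68": 8.0}.get(m, 1.0)
            cells[m] = base * np.exp(rng.normal(0, 0.2, n))
        res = ts.subsample_stability(cells, "CD68+", n_draws=200, n_cells=100, seed=1)
        assert res["mean"] > 0.99

    def test_subsamples_match_own_bulk_not_other(self, labelled_cells):
        """Subsample signatures correlate higher with their own population's
        bulk signature than with a different population's."""
        a = ts.subsample_stability(labelled_cells, "CD68+IRF8+", n_draws=100, n_cells=100, seed=2)
        bulk_other = (
            labelled_cells[labelled_cells["phenotype"] == "CD68+CD206++"][list(ts.MARKERS)]
            .mean()
            .to_numpy()
        )
        sub = labelled_cells[labelled_cells["phenotype"] == "CD68+IRF8+"]
        x = sub[list(ts.MARKERS)].to_numpy()
        rng = np.random.default_rng(2)
        idx = np.stack([rng.choice(len(x), 100, replace=False) for _ in range(100)])
        means = x[idx].mean(axis=1)
        r_cross = np.array(
            [np.corrcoef(m, bulk_other)[0, 1] for m in means]
        )
        assert np.mean(a["r"][:100] > r_cross) >= 0.99

    def test_small_population_skipped_with_warning(self, labelled_cells):
        with pytest.warns(UserWarning):
            res = ts.subsample_stability(
                labelled_cells, "CD68+IRF8+", n_draws=5, n_cells=10**7
            )
        assert np.isnan(res["mean"])


class TestKmeansPopulationCheck:
    @staticmethod
    def _blob_cells(seed=0, n_per=80):
        rng = np.random.default_rng(seed)
        frames = []
        for i, pop in enumerate(ts.TAM_LABELS):
            f = make_cells(np.zeros(n_per), np.zeros(n_per), phenotype=[pop] * n_per)
            for j, m in enumerate(ts.MARKERS):
                centre = 40.0 * ((i + j) % 7) + 3.0
                f[m] = np.exp(np.log(centre) + rng.normal(0, 0.05, n_per))
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_seven_separated_blobs_recovered(self):
        cells = self._blob_cells()
        res = ts.kmeans_population_check(cells, k_range=range(6, 9), seed=0)
        ari = res.loc[res["k"] == 7, "ari_vs_gate"].iloc[0]
        assert ari >= 0.95

    def test_duplicated_dataset_same_clusters(self):
        cells = self._blob_cells(seed=1)
        doubled = pd.concat([cells, cells], ignore_index=True)
        r1 = ts.kmeans_population_check(cells, k_range=[7], seed=0)
        r2 = ts.kmeans_population_check(doubled, k_range=[7], seed=0)
        assert r2["inertia"].iloc[0] == pytest.approx(2 * r1["inertia"].iloc[0], rel=1e-6)

    def test_k_larger_than_n_rejected(self):
        cells = self._blob_cells(n_per=2)
        with pytest.raises(ts.ConfigError):
            ts.kmeans_population_check(cells, k_range=[100])
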