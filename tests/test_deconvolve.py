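"""Unit and property tests for the deconvolution stages."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import spotsplit as ss
from oracle_utils import nb_quantile_bruteforce, phi_bruteforce
from spotsplit.deconvolve import assigned_matrix


def _matrix(arr, genes=None, barcodes=None):
    arr = np.asarray(arr)
    return ss.GeneSpotMatrix(
        counts=sp.csr_matrix(arr),
        gene_ids=genes or [f"g{i}" for i in range(arr.shape[0])],
        barcodes=barcodes or [f"b{j}" for j in range(arr.shape[1])],
    )


class TestBinarize:
    def test_positive_counts_become_one(self):
        out = ss.binarize(_matrix([[0, 3], [2, 0]]))
        assert np.array_equal(out.toarray(), [[0, 1], [1, 0]])

    def test_zero_row_stays_zero_and_idempotent(self):
        m = _matrix([[0, 0, 0], [1, 5, 0]])
        once = ss.binarize(m)
        twice = ss.binarize(once)
        assert once.toarray()[0].sum() == 0
        assert (once != twice).nnz == 0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ss.binarize(sp.csr_matrix(np.array([[1, -2]])))


class TestGeneDistance:
    def _dist(self, rows, min_prevalence=1):
        binary = sp.csr_matrix(np.asarray(rows))
        genes = [f"g{i}" for i in range(binary.shape[0])]
        return ss.gene_distance(binary, genes, min_prevalence=min_prevalence)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0, 1, 0], [1, 0, 1, 0], 0.0),  # identical -> r = 1
            ([1, 0, 1, 0], [0, 1, 0, 1], 2.0),  # complementary -> r = -1
            ([1, 1, 0, 0], [1, 0, 1, 0], 1.0),  # phi = 0 (ad - bc = 0)
        ],
    )
    def test_known_pairs(self, a, b, expected):
        dist, genes, _ = self._dist([a, b])
        assert dist[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_exclusions_and_reasons(self):
        dist, retained, excluded = self._dist(
            [[1, 1, 1, 1], [0, 0, 0, 1], [1, 0, 1, 0], [0, 1, 1, 0]],
            min_prevalence=2,
        )
        reasons = dict(excluded)
        assert reasons == {"g0": "zero variance", "g1": "low prevalence"}
        assert retained == ["g2", "g3"]

    def test_fewer_than_two_retained_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            self._dist([[1, 1, 1], [1, 0, 0]], min_prevalence=2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30 - 1))
    def test_distance_matrix_properties_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(6, 12))
        rows[0, :] = [1] * 6 + [0] * 6  # guarantee >= 2 usable genes
        rows[1, :] = [0] * 6 + [1] * 6
        binary = sp.csr_matrix(rows)
        try:
            dist, genes, _ = ss.gene_distance(binary, [f"g{i}" for i in range(6)], 1)
        except ValueError:
            return
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)
        assert dist.min() >= 0.0 and dist.max() <= 2.0
        idx = [int(g[1:]) for g in genes]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                expected = 1.0 - phi_bruteforce(rows[idx[i]], rows[idx[j]])
                assert dist[i, j] == pytest.approx(expected, abs=1e-12)


class TestClusterGenes:
    def test_two_separated_blocks_cut_at_default(self):
        d = np.full((4, 4), 2.0)
        d[np.ix_([0, 1], [0, 1])] = 0.0
        d[np.ix_([2, 3], [2, 3])] = 0.0
        np.fill_diagonal(d, 0.0)
        cs = ss.cluster_genes(d, ["a", "b", "c", "d"], cut_height=1.5)
        assert cs.assignments["a"] == cs.assignments["b"]
        assert cs.assignments["c"] == cs.assignments["d"]
        assert cs.assignments["a"] != cs.assignments["c"]

    def test_all_zero_distances_single_module(self):
        cs = ss.cluster_genes(np.zeros((3, 3)), ["a", "b", "c"], cut_height=1.5)
        assert len(cs.modules) == 1

    def test_nonpositive_cut_rejected(self):
        with pytest.raises(ValueError, match="cut_height"):
            ss.cluster_genes(np.zeros((2, 2)), ["a", "b"], cut_height=0.0)

    def test_true_modules_recovered_on_mixed_synthetic(self, small_spatial):
        # module genes of the same cell type co-occur; a cut below the
        # uncorrelated plateau (~1.0) isolates the true modules exactly
        from sklearn.metrics import adjusted_rand_score

        _, matrix, _, truth = small_spatial
        dist, retained, _ = ss.gene_distance(ss.binarize(matrix), matrix.gene_ids, 3)
        cs = ss.cluster_genes(dist, retained, cut_height=0.9)
        module_genes = [g for g in retained if truth.gene_module[g] is not None]
        ari = adjusted_rand_score(
            [truth.gene_module[g] for g in module_genes],
            [cs.assignments[g] for g in module_genes],
        )
        assert ari >= 0.9


class TestModuleSums:
    def test_single_module_equals_spot_totals(self):
        m = _matrix([[1, 2], [3, 0], [0, 4]])
        cs = ss.GeneClusterSet(
            assignments={"g0": "M1", "g1": "M1", "g2": "M1"}, excluded=[], cut_height=1.5
        )
        sums = ss.module_spot_sums(m, cs)
        assert np.array_equal(sums.loc["M1"].to_numpy(), [4, 6])

    def test_gene_order_permutation_invariant(self):
        arr = np.array([[1, 2], [3, 0], [0, 4], [2, 2]])
        cs = ss.GeneClusterSet(
            assignments={"g0": "M1", "g1": "M2", "g2": "M1", "g3": "M2"},
            excluded=[],
            cut_height=1.5,
        )
        sums1 = ss.module_spot_sums(_matrix(arr), cs)
        perm = [3, 1, 0, 2]
        m2 = ss.GeneSpotMatrix(
            counts=sp.csr_matrix(arr[perm]),
            gene_ids=[f"g{i}" for i in perm],
            barcodes=["b0", "b1"],
        )
        sums2 = ss.module_spot_sums(m2, cs)
        pd.testing.assert_frame_equal(sums1, sums2)

    def test_zero_module_row(self):
        m = _matrix([[0, 0], [3, 1]])
        cs = ss.GeneClusterSet(
            assignments={"g0": "M1", "g1": "M2"}, excluded=[], cut_height=1.5
        )
        assert ss.module_spot_sums(m, cs).loc["M1"].sum() == 0


class TestNBFit:
    def test_method_of_moments_identities(self):
        # mean 4, sample variance 8 -> dispersion 16 / 4 = 4
        values = [0, 0, 6, 6, 8, 4, 4, 4]
        x = np.asarray(values, float)
        assert x.mean() == 4.0 and x.var(ddof=1) == 8.0
        params = ss.fit_nb(values)
        assert params.family == "NB"
        assert params.mean == 4.0
        assert params.dispersion == pytest.approx(4.0)

    def test_underdispersed_sample_falls_back_to_poisson(self):
        values = [3, 4, 5, 4, 4]  # mean 4, variance 0.5 < mean
        params = ss.fit_nb(values)
        assert params.family == "Poisson"
        assert params.mean == 4.0
        assert math.isinf(params.dispersion)

    def test_large_sample_refit_recovers_truth(self):
        rng = np.random.default_rng(0)
        r, m = 2.0, 10.0
        draws = rng.negative_binomial(r, r / (r + m), size=100_000)
        params = ss.fit_nb(draws)
        assert params.mean == pytest.approx(m, rel=0.01)
        assert params.dispersion == pytest.approx(r, rel=0.10)

    def test_all_zero_sample_flagged_degenerate(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            params = ss.fit_nb([0, 0, 0])
        assert params.mean == 0.0
        assert ss.nb_quantile(params, 0.85) == 0
        assert "degenerate" in caplog.text


class TestNBQuantile:
    def test_zero_rate_poisson(self):
        assert ss.nb_quantile(ss.NBParams(0.0, math.inf, "Poisson"), 0.85) == 0

    def test_matches_empirical_quantile_of_seeded_draws(self):
        params = ss.NBParams(4.0, 4.0, "NB")
        rng = np.random.default_rng(42)
        draws = rng.negative_binomial(4.0, 4.0 / 8.0, size=1_000_000)
        empirical = int(np.percentile(draws, 85, method="inverted_cdf"))
        assert ss.nb_quantile(params, 0.85) == empirical

    def test_nondecreasing_in_q(self):
        params = ss.NBParams(7.3, 1.8, "NB")
        qs = np.linspace(0.05, 0.95, 19)
        vals = [ss.nb_quantile(params, q) for q in qs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_matches_bruteforce_cdf_summation(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            mean = float(rng.uniform(0.1, 80.0))
            disp = float(rng.uniform(0.2, 50.0)) if rng.uniform() < 0.8 else math.inf
            q = float(rng.uniform(0.05, 0.99))
            family = "Poisson" if math.isinf(disp) else "NB"
            params = ss.NBParams(mean, disp, family)
            assert ss.nb_quantile(params, q) == nb_quantile_bruteforce(mean, disp, q)

    def test_q_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="q"):
            ss.nb_quantile(ss.NBParams(4.0, 4.0, "NB"), 1.0)


class TestPresenceAndCounts:
    def _sums(self, rows, modules=None, spots=None):
        rows = np.asarray(rows)
        return pd.DataFrame(
            rows,
            index=modules or [f"M{i+1}" for i in range(rows.shape[0])],
            columns=spots or [f"b{j}" for j in range(rows.shape[1])],
        )

    def test_counts_are_floor_of_sum_over_minimum(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5.0, size=60)
        row = np.concatenate([base, [100, 350, 120]])
        deconv = ss.call_presence_and_counts(self._sums([row]))
        m = "M1"
        thr = deconv.thresholds[m]
        present = deconv.presence.loc[m]
        sums = deconv.module_sums.loc[m]
        assert (sums[present] > thr).all()
        assert int(deconv.min_sums[m]) == int(sums[present].min())
        # the spot summing exactly to the minimum yields one cell; 350 vs 100 -> 3
        assert deconv.cell_counts.loc[m, present].min() == 1
        if deconv.min_sums[m] == 100:
            b_350 = sums.index[sums == 350][0]
            assert deconv.cell_counts.loc[m, b_350] == 3

    def test_absent_spots_have_zero_cells(self):
        deconv = ss.call_presence_and_counts(self._sums([[0, 0, 1, 50, 60, 0, 2, 1]]))
        absent = ~deconv.presence.loc["M1"]
        assert (deconv.cell_counts.loc["M1", absent] == 0).all()

    def test_module_present_nowhere_is_dropped(self):
        sums = self._sums([[5, 5, 5, 5], [0, 0, 40, 2]], modules=["Mflat", "Mpeak"])
        deconv = ss.call_presence_and_counts(sums)
        assert "Mflat" in deconv.dropped_modules
        assert list(deconv.cell_counts.index) == ["Mpeak"]

    def test_raising_percentile_never_adds_presence(self):
        rng = np.random.default_rng(3)
        sums = self._sums(rng.negative_binomial(2, 0.1, size=(4, 200)))
        lo = ss.call_presence_and_counts(sums, percentile=0.80)
        hi = ss.call_presence_and_counts(sums, percentile=0.95)
        shared = [m for m in hi.presence.index if m in lo.presence.index]
        assert (hi.presence.loc[shared] <= lo.presence.loc[shared]).all().all()
        assert int(hi.presence.sum().sum()) <= int(lo.presence.sum().sum())

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError, match="percentile"):
            ss.call_presence_and_counts(self._sums([[1, 2, 3]]), percentile=1.5)


class TestSplitIntoCells:
    def test_counts_conserved_per_module_and_spot(self, small_deconvolution):
        matrix, layout, _, result = small_deconvolution
        cells = result.cells
        assigned = assigned_matrix(cells, matrix.barcodes).toarray()
        original = matrix.counts.toarray()
        gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
        modules = result.clusters.modules
        for m in result.deconv.presence.index:
            gidx = [gene_index[g] for g in modules[m]]
            for j, barcode in enumerate(matrix.barcodes):
                if result.deconv.presence.at[m, barcode]:
                    assert np.array_equal(assigned[gidx, j], original[gidx, j])
                else:
                    assert assigned[gidx, j].sum() == 0

    def test_single_cell_inherits_spot_module_counts(self):
        arr = np.zeros((2, 40), dtype=int)
        arr[0] = 3
        arr[1] = [0] * 39 + [50]  # one clear peak -> exactly one cell there
        matrix = _matrix(arr)
        layout = ss.SpotLayout(
            positions=pd.DataFrame(
                {
                    "in_tissue": 1,
                    "array_row": 0,
                    "array_col": range(40),
                    "x": np.arange(40) * 100.0,
                    "y": 0.0,
                },
                index=pd.Index(matrix.barcodes, name="barcode"),
            ),
            spot_radius=27.5,
        )
        cs = ss.GeneClusterSet(
            assignments={"g0": "M1", "g1": "M2"}, excluded=[], cut_height=1.5
        )
        sums = ss.module_spot_sums(matrix, cs)
        deconv = ss.call_presence_and_counts(sums)
        cells = ss.split_into_cells(matrix, cs, deconv, layout, seed=0)
        peak_cells = [i for i, c in enumerate(cells.clusters) if c == "M2"]
        assert len(peak_cells) == 1
        assert cells.counts[1, peak_cells[0]] == 50

    def test_cells_placed_within_spot_radius(self, small_deconvolution):
        matrix, layout, _, result = small_deconvolution
        cells = result.cells
        pos = layout.positions
        dx = cells.x - pos.loc[cells.source_barcodes, "x"].to_numpy()
        dy = cells.y - pos.loc[cells.source_barcodes, "y"].to_numpy()
        assert np.all(dx**2 + dy**2 <= layout.spot_radius**2 + 1e-9)

    def test_missing_barcode_in_layout_rejected(self, small_deconvolution):
        matrix, layout, _, result = small_deconvolution
        bad_layout = ss.SpotLayout(layout.positions.iloc[:-1], layout.spot_radius)
        with pytest.raises(ValueError, match="layout missing"):
            ss.split_into_cells(
                matrix, result.clusters, result.deconv, bad_layout, seed=0
            )


class TestRunDeconvolution:
    def test_empty_matrix_rejected(self):
        matrix = _matrix(np.zeros((3, 4), dtype=int))
        layout = ss.SpotLayout(
            positions=pd.DataFrame(
                {
                    "in_tissue": 1,
                    "array_row": 0,
                    "array_col": range(4),
                    "x": np.arange(4) * 100.0,
                    "y": 0.0,
                },
                index=pd.Index(matrix.barcodes, name="barcode"),
            ),
            spot_radius=27.5,
        )
        with pytest.raises(ValueError, match="empty"):
            ss.run_deconvolution(matrix, layout)

    def test_same_seed_identical_output(self, small_spatial):
        _, matrix, layout, _ = small_spatial
        cfg = ss.DeconvolutionConfig(cut_height=0.9, seed=7)
        r1 = ss.run_deconvolution(matrix, layout, cfg)
        r2 = ss.run_deconvolution(matrix, layout, cfg)
        assert r1.cells.cell_ids == r2.cells.cell_ids
        assert (r1.cells.counts != r2.cells.counts).nnz == 0
        assert np.array_equal(r1.cells.x, r2.cells.x)

    def test_report_accounts_for_all_count_mass(self, small_deconvolution):
        matrix, _, _, result = small_deconvolution
        rep = result.report
        assert rep["assigned_counts"] + rep["unassigned_counts"] == rep["total_counts"]
        assert rep["total_counts"] == int(matrix.counts.sum())
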