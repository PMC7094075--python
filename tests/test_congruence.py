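import numpy as np
import pytest

from paramicro import (
    SimulationParams,
    leave_one_out,
    paired_sample_ids,
    pcoa,
    procrustes_fit,
    protest,
    simulate_paired_communities,
    weighted_unifrac,
)
from paramicro.congruence import drill_down


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestProcrustesFit:
    def test_similarity_transform_gives_perfect_fit(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 2))
        Y = 3.7 * (X @ rotation(np.deg2rad(37)).T) + np.array([5.0, -2.0])
        res = procrustes_fit(X, Y)
        assert res.t0 == pytest.approx(1.0, abs=1e-12)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-12)

    def test_pure_scaling_three_points(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1]])
        assert procrustes_fit(X, 2 * X).t0 == pytest.approx(1.0, abs=1e-12)

    def test_reflection_allowed(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 2))
        Y = X @ np.array([[1.0, 0], [0, -1.0]])
        assert procrustes_fit(X, Y).t0 == pytest.approx(1.0, abs=1e-12)

    def test_random_pairing_gives_small_t0(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(100):
            X = rng.standard_normal((200, 2))
            Y = X[rng.permutation(200)]
            vals.append(procrustes_fit(X, Y).t0)
        assert np.mean(vals) < 0.3

    def test_symmetry_of_t0(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X, Y = rng.random((8, 2)), rng.random((8, 2))
            assert procrustes_fit(X, Y).t0 == pytest.approx(
                procrustes_fit(Y, X).t0, abs=1e-10
            )

    def test_invariance_to_similarity_transform_of_inputs(self):
        rng = np.random.default_rng(4)
        X, Y = rng.random((9, 2)), rng.random((9, 2))
        base = procrustes_fit(X, Y).t0
        X2 = 0.3 * (X @ rotation(1.1).T) + 7
        Y2 = 5.0 * (Y @ rotation(-0.4).T) - 2
        assert procrustes_fit(X2, Y2).t0 == pytest.approx(base, abs=1e-10)

    def test_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(5)
        X, Y = rng.random((10, 2)), rng.random((10, 2))
        _, _, disparity = scipy_procrustes(X, Y)
        res = procrustes_fit(X, Y)
        assert res.m12_squared == pytest.approx(disparity, abs=1e-10)
        assert res.t0 == pytest.approx(np.sqrt(1 - disparity), abs=1e-10)

    def test_matches_vegan_protest(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(31)
        X, Y = rng.random((10, 2)), rng.random((10, 2))
        np.savetxt(tmp_path / "X.tsv", X)
        np.savetxt(tmp_path / "Y.tsv", Y)
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'X <- as.matrix(read.table("{tmp_path}/X.tsv"))\n'
            f'Y <- as.matrix(read.table("{tmp_path}/Y.tsv"))\n'
            'p <- protest(X, Y, permutations = 99)\n'
            'cat(sprintf("%.12f %.12f\\n", p$t0, p$ss))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        t0_ref, ss_ref = map(float, out.stdout.split())
        res = procrustes_fit(X, Y)
        assert res.t0 == pytest.approx(t0_ref, abs=1e-10)
        assert res.m12_squared == pytest.approx(ss_ref, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="row mismatch"):
            procrustes_fit(np.zeros((4, 2)), np.zeros((5, 2)))
        with pytest.raises(ValueError, match="at least 2"):
            procrustes_fit(np.ones((5, 1)), np.ones((5, 1)))


class TestProtest:
    def test_perfect_fit_gives_minimal_p(self):
        rng = np.random.default_rng(6)
        X = rng.random((12, 2))
        res = protest(X, 2.0 * (X @ rotation(0.5).T), n_permutations=99, seed=0)
        assert res.permutation_p == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X, Y = rng.random((12, 2)), rng.random((12, 2))
        a = protest(X, Y, 199, seed=3).permutation_p
        b = protest(X, Y, 199, seed=3).permutation_p
        assert a == b

    def test_type_one_error_near_nominal_under_gaussian_null(self):
        # independent configurations: rejection rate at 0.05 stays inside the
        # 95% binomial envelope for 200 trials ([0.0198, 0.0802])
        rng = np.random.default_rng(8)
        rej = 0
        n = 200
        for i in range(n):
            X = rng.standard_normal((12, 2))
            Y = rng.standard_normal((12, 2))
            if protest(X, Y, 99, seed=1000 + i).permutation_p <= 0.05:
                rej += 1
        assert 0.0198 <= rej / n <= 0.0802


class TestPairing:
    def test_pairs_sorted_and_matched(self):
        ds = simulate_paired_communities(
            SimulationParams(n_taxa=24, community_types=("PR", "IIR"), seed=1)
        )
        ids_p, ids_h = paired_sample_ids(ds.bundle.metadata, "PR", "IIR")
        assert len(ids_p) == len(ids_h) == 12
        md = ds.bundle.metadata
        for a, b in zip(ids_p, ids_h):
            assert md.loc[a, "site_id"] == md.loc[b, "site_id"]
            assert md.loc[a, "replicate"] == md.loc[b, "replicate"]
            # infected-unit organs share the excavated specimen
            assert md.loc[a, "specimen_id"] == md.loc[b, "specimen_id"]


def _paired_setup(seed, **kw):
    params = SimulationParams(n_taxa=40, community_types=("PR", "IIR"), seed=seed, **kw)
    ds = simulate_paired_communities(params)
    md = ds.bundle.metadata
    ids_p, ids_h = paired_sample_ids(md, "PR", "IIR")
    tp = ds.bundle.table.select_samples(ids_p)
    th = ds.bundle.table.select_samples(ids_h)
    H = pcoa(weighted_unifrac(th, ds.bundle.tree)).axes(2)
    P = pcoa(weighted_unifrac(tp, ds.bundle.tree)).axes(2)
    t0 = procrustes_fit(H, P).t0
    return ds, tp, H, t0


class TestLeaveOneOut:
    def test_zero_abundance_clade_has_exactly_zero_delta(self):
        from paramicro import FeatureTable

        ds, tp, H, t0 = _paired_setup(11)
        # plant a phantom clade: zero out one feature and give it its own phylum
        counts = tp.counts.copy()
        counts[-1, :] = 0
        tp0 = FeatureTable(tp.feature_ids, tp.sample_ids, counts)
        tax = ds.bundle.taxonomy.copy()
        tax.loc[tp.feature_ids[-1], "phylum"] = "GHOST"
        from paramicro import pcoa as _pcoa, weighted_unifrac as _wu

        t0_new = procrustes_fit(H, _pcoa(_wu(tp0, ds.bundle.tree)).axes(2)).t0
        recs = leave_one_out(tp0, tax, ds.bundle.tree, H, t0_new, rank="phylum")
        ghost = next(r for r in recs if r.clade == "GHOST")
        assert ghost.delta_t == 0.0

    def test_delta_bounded(self):
        ds, tp, H, t0 = _paired_setup(12)
        recs = leave_one_out(tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0)
        assert recs
        for r in recs:
            if not r.skipped:
                assert -t0 - 1e-9 <= r.delta_t <= 1 - t0 + 1e-9

    def test_driver_clade_most_negative_delta(self):
        ds, tp, H, t0 = _paired_setup(
            13, kappa=0.95, driver_clade_fraction=1.0,
            noise_sd=0.4, overdispersion=0.2, site_sd=0.1,
        )
        recs = [
            r
            for r in leave_one_out(tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0)
            if not r.skipped
        ]
        best = min(recs, key=lambda r: r.delta_t)
        assert best.clade == ds.driver_phylum

    def test_unknown_rank_errors(self):
        ds, tp, H, t0 = _paired_setup(14)
        with pytest.raises(KeyError):
            leave_one_out(tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0, rank="kingdom")


class TestDrillDown:
    def test_top_k_zero_is_empty(self):
        ds, tp, H, t0 = _paired_setup(15)
        recs = leave_one_out(tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0)
        assert drill_down(recs, tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0, top_k=0) == []

    def test_single_phylum_covers_all_orders(self):
        params = SimulationParams(
            n_taxa=24, n_phyla=1, orders_per_phylum=3, community_types=("PR", "IIR"), seed=16
        )
        ds = simulate_paired_communities(params)
        md = ds.bundle.metadata
        ids_p, ids_h = paired_sample_ids(md, "PR", "IIR")
        tp = ds.bundle.table.select_samples(ids_p)
        th = ds.bundle.table.select_samples(ids_h)
        H = pcoa(weighted_unifrac(th, ds.bundle.tree)).axes(2)
        t0 = procrustes_fit(H, pcoa(weighted_unifrac(tp, ds.bundle.tree)).axes(2)).t0
        recs = leave_one_out(tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0)
        drill = drill_down(recs, tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0, top_k=1)
        assert {r.clade for r in drill} == set(ds.bundle.taxonomy["order"].unique())

    def test_driver_order_ranks_first_among_orders(self):
        ds, tp, H, t0 = _paired_setup(
            17, kappa=0.95, driver_clade_fraction=1.0,
            noise_sd=0.4, overdispersion=0.2, site_sd=0.1,
        )
        recs = leave_one_out(tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0)
        drill = [
            r
            for r in drill_down(recs, tp, ds.bundle.taxonomy, ds.bundle.tree, H, t0)
            if not r.skipped
        ]
        best = min(drill, key=lambda r: r.delta_t)
        assert best.clade == ds.driver_order
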