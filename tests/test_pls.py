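"""Behavioral PLS: correlation map, SVD, permutation, bootstrap, clusters."""

import numpy as np
import pandas as pd
import pytest

from tprsmap.pls import (
    BehavioralPLS,
    bootstrap_saliences,
    brainscores,
    build_correlation_matrix,
    cluster_report,
    permutation_test,
    pls_svd,
)
from tprsmap.simulate import ActivationData, SimulationConfig, simulate_brain_data


def make_activations(matrices, groups, dims=None):
    n_vox = next(iter(matrices.values())).shape[1]
    if dims is None:
        dims = (n_vox, 1, 1)
    xs, ys, zs = np.unravel_index(np.arange(n_vox), dims)
    vox = pd.DataFrame({"voxel_id": [f"V{i}" for i in range(n_vox)],
                        "x": xs, "y": ys, "z": zs})
    n = next(iter(matrices.values())).shape[0]
    ids = [f"s{i}" for i in range(n)]
    return ActivationData(matrices=matrices, subject_ids=ids, voxel_table=vox,
                          group=pd.Series(list(groups), index=ids))


def planted_study(n=120, n_vox=100, r=-0.4, noise=1.0, seed=0, signal_frac=0.3):
    cfg = SimulationConfig(
        n_subjects=n, n_variants=20, n_voxels=n_vox, grid_dims=(5, 5, n_vox // 25),
        planted_effects={("female", "neutral_faces"): r},
        signal_fraction=signal_frac, noise_sd=noise, seed=seed,
    )
    rng = np.random.default_rng(seed)
    score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
    groups = ["female" if i < n // 2 else "male" for i in range(n)]
    act, truth = simulate_brain_data(score, groups, cfg)
    return act, score, truth


class TestCorrelationMatrix:
    def test_voxel_equal_to_score_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        score = rng.normal(size=12)
        mat = rng.normal(size=(12, 4))
        mat[:6, 0] = score[:6]  # group A, first voxel mirrors the score
        act = make_activations({"c1": mat}, ["A"] * 6 + ["B"] * 6)
        R, rows = build_correlation_matrix(
            act, pd.Series(score, index=act.subject_ids)
        )
        assert rows[0] == ("A", "c1")
        assert R[0, 0] == pytest.approx(1.0)

    def test_constant_voxel_gets_zero_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(10, 3))
        mat[:, 2] = 5.0
        act = make_activations({"c1": mat}, ["A"] * 10)
        with caplog.at_level("WARNING"):
            R, _ = build_correlation_matrix(
                act, pd.Series(rng.normal(size=10), index=act.subject_ids)
            )
        assert R[0, 2] == 0.0
        assert "zero-variance" in caplog.text

    def test_matches_per_cell_pearson_loop(self):
        rng = np.random.default_rng(2)
        n, n_vox = 30, 40
        mats = {c: rng.normal(size=(n, n_vox)) for c in ("c1", "c2", "c3")}
        groups = ["A"] * 15 + ["B"] * 15
        act = make_activations(mats, groups, dims=(4, 5, 2))
        score = pd.Series(rng.normal(size=n), index=act.subject_ids)
        R, rows = build_correlation_matrix(act, score)
        for r_i, (g, c) in enumerate(rows):
            ix = [i for i, gg in enumerate(groups) if gg == g]
            for v in range(n_vox):
                expected = np.corrcoef(score.iloc[ix], mats[c][ix, v])[0, 1]
                assert abs(R[r_i, v] - expected) < 1e-12

    def test_small_group_rejected(self):
        rng = np.random.default_rng(3)
        act = make_activations({"c": rng.normal(size=(5, 3))}, ["A"] * 3 + ["B"] * 2)
        with pytest.raises(ValueError, match="fewer than 3"):
            build_correlation_matrix(
                act, pd.Series(rng.normal(size=5), index=act.subject_ids)
            )


class TestSVD:
    def test_rank_one_recovery(self):
        u = np.array([1.0, -2.0, 0.5])
        v = np.random.default_rng(4).normal(size=20)
        v /= np.linalg.norm(v)
        R = np.outer(u, v)
        res = pls_svd(R)
        assert res.singular_values[0] == pytest.approx(np.linalg.norm(u))
        assert res.pct_crossblock[0] == pytest.approx(100.0)
        cos = abs(res.voxel_saliences[:, 0] @ v)
        assert cos == pytest.approx(1.0)

    def test_squared_singular_values_match_eigensolver(self):
        rng = np.random.default_rng(5)
        R = rng.normal(size=(6, 50))
        res = pls_svd(R)
        evals = np.sort(np.linalg.eigvalsh(R @ R.T))[::-1]
        np.testing.assert_allclose(res.singular_values**2, evals, rtol=1e-8)

    def test_sign_invariance_of_spectrum(self):
        rng = np.random.default_rng(6)
        R = rng.normal(size=(4, 30))
        r1, r2 = pls_svd(R), pls_svd(-R)
        np.testing.assert_allclose(r1.singular_values, r2.singular_values)
        np.testing.assert_allclose(r1.pct_crossblock, r2.pct_crossblock)

    def test_reconstruction(self):
        rng = np.random.default_rng(7)
        R = rng.normal(size=(5, 25))
        res = pls_svd(R)
        recon = (
            res.behavior_saliences
            @ np.diag(res.singular_values)
            @ res.voxel_saliences.T
        )
        np.testing.assert_allclose(recon, R, atol=1e-10)

    def test_sign_convention_max_entry_positive(self):
        rng = np.random.default_rng(8)
        res = pls_svd(rng.normal(size=(4, 30)))
        for k in range(res.voxel_saliences.shape[1]):
            col = res.voxel_saliences[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pls_svd(np.zeros((3, 10)))


class TestPermutation:
    def test_strong_signal_attains_p_floor(self):
        act, score, _ = planted_study(n=200, r=-0.6, noise=0.5, seed=1)
        p = permutation_test(act, score, n_perm=99, seed=0)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_seed_determinism(self):
        act, score, _ = planted_study(n=60, seed=2)
        p1 = permutation_test(act, score, n_perm=50, seed=5)
        p2 = permutation_test(act, score, n_perm=50, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_p_values_within_add_one_bounds(self):
        act, score, _ = planted_study(n=60, r=0.0, seed=3)
        p = permutation_test(act, score, n_perm=20, seed=1)
        assert np.all(p >= 1 / 21) and np.all(p <= 1.0)


class TestBootstrap:
    def test_noiseless_signal_voxels_have_extreme_bsr(self):
        act, score, truth = planted_study(n=80, r=-0.5, noise=0.0, seed=4)
        bsr, _ = bootstrap_saliences(act, score, n_boot=50, seed=0)
        sig = truth.signal_voxels
        assert np.all(np.abs(bsr[sig, 0]) >= 2.5)

    def test_bsr_sign_matches_salience_sign(self):
        act, score, _ = planted_study(n=100, seed=5)
        res = pls_svd(*build_correlation_matrix(act, score))
        bsr, _ = bootstrap_saliences(act, score, n_boot=60, seed=1, observed=res)
        nz = res.voxel_saliences[:, 0] != 0
        assert np.all(
            np.sign(bsr[nz, 0]) == np.sign(res.voxel_saliences[nz, 0])
        )

    def test_behavior_ci_brackets_planted_correlation(self):
        act, score, _ = planted_study(n=200, r=-0.5, noise=1.0, seed=6)
        res = pls_svd(*build_correlation_matrix(act, score))
        _, ci = bootstrap_saliences(act, score, n_boot=200, seed=2, observed=res)
        lo, hi = ci[(("female", "neutral_faces"), 0)]
        assert lo <= -0.2 and hi <= 0.0  # negative association, asymmetric CI

    def test_seed_determinism(self):
        act, score, _ = planted_study(n=60, seed=7)
        b1, c1 = bootstrap_saliences(act, score, n_boot=30, seed=9)
        b2, c2 = bootstrap_saliences(act, score, n_boot=30, seed=9)
        np.testing.assert_array_equal(b1, b2)
        assert c1 == c2


class TestBrainscores:
    def test_activation_equal_to_salience_projects_to_one(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        mat = np.vstack([v, np.zeros(30), rng.normal(size=30)])
        act = make_activations({"c": mat}, ["A"] * 3)
        bs = brainscores(act, v)
        assert bs["c"].iloc[0] == pytest.approx(1.0)
        assert bs["c"].iloc[1] == pytest.approx(0.0)

    def test_matches_explicit_summation(self):
        rng = np.random.default_rng(10)
        mats = {c: rng.normal(size=(8, 15)) for c in ("c1", "c2")}
        act = make_activations(mats, ["A"] * 8, dims=(3, 5, 1))
        v = rng.normal(size=15)
        bs = brainscores(act, v)
        for c in mats:
            for i in range(8):
                assert bs[c].iloc[i] == pytest.approx(
                    sum(mats[c][i, j] * v[j] for j in range(15)), abs=1e-12
                )


class TestClusters:
    def _table(self, dims):
        xs, ys, zs = np.unravel_index(np.arange(np.prod(dims)), dims)
        return pd.DataFrame({"voxel_id": [f"V{i}" for i in range(np.prod(dims))],
                             "x": xs, "y": ys, "z": zs})

    def test_isolated_voxel_below_min_size_not_reported(self):
        vox = self._table((5, 5, 5))
        bsr = np.zeros(125)
        bsr[0] = 5.0
        assert cluster_report(bsr, vox, min_cluster_size=20).empty
        # strict '>' also excludes a cluster of exactly min size
        assert cluster_report(bsr, vox, min_cluster_size=0).shape[0] == 1
        assert cluster_report(bsr, vox, min_cluster_size=1).empty

    def test_solid_block_is_one_cluster(self):
        dims = (5, 5, 5)
        vox = self._table(dims)
        bsr = np.zeros(125)
        grid = np.zeros(dims)
        grid[1:4, 1:4, 1:4] = 3.0
        bsr = grid.reshape(-1)
        df = cluster_report(bsr, vox, min_cluster_size=20)
        assert len(df) == 1
        assert df["n_voxels"].iloc[0] == 27
        assert df["sign"].iloc[0] == 1

    def test_positive_and_negative_components_kept_separate(self):
        dims = (4, 4, 4)
        vox = self._table(dims)
        grid = np.zeros(dims)
        grid[:2] = 4.0
        grid[2:] = -4.0
        df = cluster_report(grid.reshape(-1), vox, min_cluster_size=10)
        assert sorted(df["sign"]) == [-1, 1]

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        dims = (6, 6, 6)
        vox = self._table(dims)
        bsr = rng.normal(scale=2.0, size=216)
        df = cluster_report(bsr, vox, threshold=2.5, min_cluster_size=0,
                            connectivity=6)

        def flood(mask):
            grid = mask.reshape(dims)
            seen = np.zeros(dims, bool)
            comps = []
            for start in zip(*np.nonzero(grid)):
                if seen[start]:
                    continue
                stack, comp = [start], []
                seen[start] = True
                while stack:
                    cur = stack.pop()
                    comp.append(cur)
                    for d in range(3):
                        for step in (-1, 1):
                            nxt = list(cur)
                            nxt[d] += step
                            nxt = tuple(nxt)
                            if all(0 <= nxt[i] < dims[i] for i in range(3)) \
                                    and grid[nxt] and not seen[nxt]:
                                seen[nxt] = True
                                stack.append(nxt)
                comps.append(sorted(comp))
            return sorted(comps)

        expected = flood(bsr > 2.5) + flood(bsr < -2.5)
        got = []
        for _, row in df.iterrows():
            members = [int(v[1:]) for v in row["member_voxel_ids"]]
            coords = sorted(
                tuple(np.unravel_index(m, dims)[i] for i in range(3))
                if False else tuple(int(c) for c in np.unravel_index(m, dims))
                for m in members
            )
            got.append(coords)
        assert sorted(got) == sorted(expected)


class TestEstimator:
    def test_full_fit_recovers_planted_lv(self):
        act, score, truth = planted_study(n=200, r=-0.4, noise=1.0, seed=12,
                                          n_vox=100, signal_frac=0.3)
        est = BehavioralPLS(n_perm=100, n_boot=100, random_state=3).fit(act, score)
        cos = abs(est.voxel_saliences_[:, 0] @ truth.true_voxel_salience)
        assert cos > 0.8
        assert est.perm_p_[0] <= 0.05
        # planted cell is (female, neutral_faces) with a negative weight
        r_i = est.rows_.index(("female", "neutral_faces"))
        lead = est.behavior_saliences_[r_i, 0]
        others = np.delete(est.behavior_saliences_[:, 0], r_i)
        assert abs(lead) > np.max(np.abs(others))
        assert est.clusters_ is not None and len(est.clusters_) >= 1

    def test_pct_crossblock_sums_to_100(self):
        act, score, _ = planted_study(n=60, seed=13)
        res = pls_svd(*build_correlation_matrix(act, score))
        assert res.pct_crossblock.sum() == pytest.approx(100.0, abs=1e-6)

    def test_save_result_writes_tsvs(self, tmp_path):
        act, score, _ = planted_study(n=60, seed=14)
        est = BehavioralPLS(n_perm=20, n_boot=20, random_state=1).fit(act, score)
        from tprsmap.pls import save_pls_result

        save_pls_result(est.result_, tmp_path)
        for f in ("singular_values.tsv", "behavior_saliences.tsv",
                  "voxel_saliences.tsv", "bsr.tsv", "brainscores_LV1.tsv",
                  "clusters.tsv"):
            assert (tmp_path / f).exists()
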