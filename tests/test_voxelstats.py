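import numpy as np
import pandas as pd
import pytest

from brainpad_lab import clinstats as cs
from brainpad_lab import voxelstats as vx
from brainpad_lab.morphometry import VoxelGrid


def sphere_mask(n=10, frac=0.49):
    ax = np.arange(n) - (n - 1) / 2
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (xx**2 + yy**2 + zz**2) <= (frac * n) ** 2


def null_problem(n_subj=40, n=10, seed=0):
    rng = np.random.default_rng(seed)
    mask = sphere_mask(n)
    V = int(mask.sum())
    stack = rng.standard_normal((n_subj, V))
    design = pd.DataFrame(
        {
            "brain_pad": rng.normal(2.0, 2.0, n_subj),
            "age": rng.uniform(40, 80, n_subj),
            "sex": rng.integers(0, 2, n_subj).astype(float),
        }
    )
    affine = np.diag([8.0, 8.0, 8.0, 1.0])
    return stack, design, mask, affine


class TestMassuniFit:
    def test_single_voxel_matches_clinstats_ols(self):
        stack, design, mask, affine = null_problem(seed=1)
        stat = vx.massuni_fit(stack, design, "brain_pad", mask, affine)
        v = 17
        df = design.assign(y=stack[:, v])
        tab = cs.fit_ols("y", ["brain_pad", "age", "sex"], df)
        assert stat.t[v] == pytest.approx(tab.coef.loc["brain_pad", "t"], abs=1e-10)
        assert stat.df == tab.df_resid

    def test_null_t_map_moments(self):
        # pooled over voxels and simulations, t ~ Student t(df)
        ts = []
        for seed in range(30):
            stack, design, mask, affine = null_problem(n_subj=30, seed=seed)
            stat = vx.massuni_fit(stack, design, "brain_pad", mask, affine)
            ts.append(stat.t)
        ts = np.concatenate(ts)
        df = 30 - 4
        assert abs(ts.mean()) < 0.02
        assert ts.var() == pytest.approx(df / (df - 2), rel=0.05)

    def test_injected_signal_localizes(self):
        stack, design, mask, affine = null_problem(n_subj=60, seed=2)
        pad = design["brain_pad"].to_numpy()
        block = np.zeros(mask.sum(), dtype=bool)
        block[10:30] = True
        stack[:, block] += 0.8 * pad[:, None]
        stat = vx.massuni_fit(stack, design, "brain_pad", mask, affine)
        assert block[np.nanargmax(np.abs(stat.t))]

    def test_zero_variance_voxel_gets_nan(self):
        stack, design, mask, affine = null_problem(seed=3)
        stack[:, 5] = 0.7
        stat = vx.massuni_fit(stack, design, "brain_pad", mask, affine)
        assert np.isnan(stat.t[5])

    def test_rank_deficient_design_rejected(self):
        stack, design, mask, affine = null_problem(seed=4)
        design["dup"] = design["brain_pad"]
        with pytest.raises(ValueError, match="rank"):
            vx.massuni_fit(stack, design, "brain_pad", mask, affine)


class TestFWE:
    def test_corrected_p_monotone_in_abs_t(self):
        stack, design, mask, affine = null_problem(n_subj=30, seed=5)
        p_corr, t_obs = vx.fwe_correct(stack, design, "brain_pad", n_perm=150, seed=0)
        order = np.argsort(-np.abs(t_obs))
        assert (np.diff(p_corr[order]) >= -1e-12).all()

    def test_deterministic_given_seed(self):
        stack, design, mask, affine = null_problem(n_subj=25, seed=6)
        p1, _ = vx.fwe_correct(stack, design, "brain_pad", n_perm=120, seed=9)
        p2, _ = vx.fwe_correct(stack, design, "brain_pad", n_perm=120, seed=9)
        assert np.array_equal(p1, p2)

    def test_strong_effect_survives_correction(self):
        stack, design, mask, affine = null_problem(n_subj=80, seed=7)
        pad = design["brain_pad"].to_numpy()
        z = (pad - pad.mean()) / pad.std()
        stack[:, 40:60] += 1.5 * z[:, None]
        p_corr, t_obs = vx.fwe_correct(stack, design, "brain_pad", n_perm=200, seed=1)
        assert p_corr[40:60].min() < 0.05

    def test_too_few_permutations_rejected(self):
        stack, design, mask, affine = null_problem(seed=8)
        with pytest.raises(ValueError, match="n_perm"):
            vx.fwe_correct(stack, design, "brain_pad", n_perm=50)


class TestClusters:
    def make_stat(self, t_vol, mask, spacing=8.0):
        affine = np.diag([spacing] * 3 + [1.0])
        affine[:3, 3] = -spacing * (np.array(mask.shape) - 1) / 2  # centred origin
        return vx.StatMap(t=t_vol[mask], df=50, contrast="brain_pad", mask=mask, affine=affine)

    def test_no_suprathreshold_voxels_empty_table(self):
        mask = sphere_mask(8)
        stat = self.make_stat(np.ones(mask.shape), mask)
        p = np.ones(int(mask.sum()))
        assert vx.extract_clusters(stat, p, alpha=0.05, min_extent_voxels=1) == []

    def test_small_blob_dropped_by_extent_rule(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        t_vol = np.zeros(mask.shape)
        t_vol[2:3, 2:3, 2:7] = 5.0  # 5-voxel blob
        p = np.ones(int(mask.sum()))
        p[t_vol[mask] > 0] = 0.001
        stat = self.make_stat(t_vol, mask)
        assert vx.extract_clusters(stat, p, alpha=0.05, min_extent_voxels=100) == []
        kept = vx.extract_clusters(stat, p, alpha=0.05, min_extent_voxels=5)
        assert len(kept) == 1 and kept[0].n_voxels == 5

    def test_200_voxel_blob_size_in_ml_and_peak_location(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        t_vol = np.zeros(mask.shape)
        t_vol[2:7, 2:6, 2:12] = -4.0  # 5*4*10 -> clipped to 5*4*8 = 160... use exact
        t_vol[:] = 0.0
        t_vol[1:6, 1:6, 1:9] = -4.0  # 5*5*8 = 200 voxels
        peak = (3, 3, 4)
        t_vol[peak] = -9.0
        p = np.ones(int(mask.sum()))
        p[t_vol[mask] != 0] = 0.01
        stat = self.make_stat(t_vol, mask, spacing=8.0)
        recs = vx.extract_clusters(stat, p, alpha=0.05, min_extent_voxels=100)
        assert len(recs) == 1
        r = recs[0]
        assert r.n_voxels == 200
        assert r.size_ml == pytest.approx(200 * 0.512)
        assert r.sign == "negative"
        assert r.peak_t == -9.0
        world = stat.affine @ np.array([*peak, 1.0])
        assert r.peak_xyz_mm == pytest.approx(tuple(world[:3]))
        assert r.hemisphere == ("L" if world[0] < 0 else "R")

    def test_cluster_sizes_invariant_to_component_labelling(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        t_vol = np.zeros(mask.shape)
        t_vol[0:2, 0:2, 0:2] = 3.0
        t_vol[7:10, 7:10, 7:10] = 4.0
        p = np.ones(int(mask.sum()))
        p[t_vol[mask] > 0] = 0.01
        stat = self.make_stat(t_vol, mask)
        recs = vx.extract_clusters(stat, p, alpha=0.05, min_extent_voxels=2)
        assert sorted(r.n_voxels for r in recs) == [8, 27]


class TestSlopeContrast:
    def interaction_problem(self, slope_g0=0.0, slope_g1=0.0, n_per=40, seed=0):
        rng = np.random.default_rng(seed)
        mask = sphere_mask(8)
        V = int(mask.sum())
        n = 2 * n_per
        group = np.repeat([0.0, 1.0], n_per)
        pad = rng.normal(2, 2, n)
        stack = rng.standard_normal((n, V))
        region = np.zeros(V, dtype=bool)
        region[:15] = True
        slope = np.where(group == 0, slope_g0, slope_g1)
        stack[:, region] += (slope * pad)[:, None]
        design = pd.DataFrame({"group": group, "brain_pad": pad, "age": rng.uniform(40, 80, n)})
        return stack, design, mask, np.eye(4), region

    def test_label_swap_flips_sign(self):
        stack, design, mask, affine, _ = self.interaction_problem(0.5, 0.0, seed=1)
        s1 = vx.slope_contrast(stack, design, mask, affine)
        flipped = design.assign(group=1.0 - design["group"])
        s2 = vx.slope_contrast(stack, flipped, mask, affine)
        assert np.allclose(s1.t, -s2.t, atol=1e-8)

    def test_injected_interaction_localizes(self):
        stack, design, mask, affine, region = self.interaction_problem(-0.8, 0.0, n_per=60, seed=2)
        stat = vx.slope_contrast(stack, design, mask, affine)
        assert region[np.nanargmax(np.abs(stat.t))]

    def test_equal_slopes_give_null_interaction(self):
        maxima = []
        for seed in range(10):
            stack, design, mask, affine, _ = self.interaction_problem(0.4, 0.4, seed=seed)
            stat = vx.slope_contrast(stack, design, mask, affine)
            maxima.append(np.abs(stat.t).mean())
        # mean |t| of a central t-distribution is ~0.8 for moderate df
        assert np.mean(maxima) < 1.0

    def test_small_group_rejected(self):
        stack, design, mask, affine, _ = self.interaction_problem(n_per=40)
        design.loc[design.index[:75], "group"] = 1.0
        with pytest.raises(ValueError, match="10"):
            vx.slope_contrast(stack, design, mask, affine)


class TestROICorrelation:
    def make_maps(self, values_by_subject, mask):
        return {
            sid: {"GM": VoxelGrid(vol, (8.0,) * 3, mask, tissue="GM")}
            for sid, vol in values_by_subject.items()
        }

    def test_exactly_linear_gives_unit_correlation(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        pads = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        maps = self.make_maps(
            {s: np.full((4, 4, 4), 0.5 - 0.05 * pads[s]) for s in pads.index}, mask
        )
        groups = pd.Series(["PD"] * 4, index=pads.index)
        out = vx.roi_correlation(mask, maps, pads, groups)
        r, p = out["PD"]
        assert r == pytest.approx(-1.0)

    def test_constant_pad_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        pads = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        rng = np.random.default_rng(0)
        maps = self.make_maps({s: rng.random((4, 4, 4)) for s in pads.index}, mask)
        groups = pd.Series(["PD"] * 3, index=pads.index)
        with pytest.raises(ValueError, match="constant"):
            vx.roi_correlation(mask, maps, pads, groups)

    def test_empty_cluster_rejected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            vx.roi_correlation(mask, {}, pd.Series(dtype=float), pd.Series(dtype=str))

    def test_null_pad_gives_small_correlation(self):
        rng = np.random.default_rng(1)
        mask = np.ones((4, 4, 4), dtype=bool)
        ids = [f"s{i}" for i in range(200)]
        pads = pd.Series(rng.normal(size=200), index=ids)
        maps = self.make_maps({s: rng.random((4, 4, 4)) for s in ids}, mask)
        groups = pd.Series(["PD"] * 200, index=ids)
        r, p = vx.roi_correlation(mask, maps, pads, groups)["PD"]
        assert abs(r) < 0.2
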