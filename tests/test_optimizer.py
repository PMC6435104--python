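import dataclasses

import numpy as np
import pandas as pd
import pytest

from boldopt import constants
from boldopt.bs_core import DEFAULT_CONFIG, voxel_bs, wellshimmed_loss
from boldopt.field_io import GradientField
from boldopt.optimizer import (MAX_WELLSHIMMED_LOSS, ROISet, bs_volume,
                               cross_roi_impact, evaluate_grid,
                               feasible_sets, optimize_roi,
                               optimize_voxelwise, per_subject_optima,
                               tie_key)
from boldopt.protocol import (AdjustableParams, ParameterGrid, Polarity,
                              REFERENCE_PARAMS, build_grid, default_grid,
                              get_preset)

import oracle

SMALL_GRID = build_grid(zshim=(-2, 2, 0.5), tilt=(-30, 30, 15))


def gradfield_from_arrays(gx, gy, gz, mask=None):
    return GradientField(gx=gx, gy=gy, gz=gz, voxel_size=(3.0, 3.0, 3.0),
                         mask=mask)


class TestFeasibleSets:
    def test_all_satisfy_constraint(self, standard_protocol):
        for p in feasible_sets(default_grid(), standard_protocol):
            assert wellshimmed_loss(p, standard_protocol) \
                <= MAX_WELLSHIMMED_LOSS

    def test_strong_shims_excluded(self, standard_protocol):
        # at 3 mm slices, |M| = 1.5 mT/m*ms loses ~17 % in well-shimmed
        # tissue and must be filtered; |M| = 1.0 (~8 %) survives
        moments = {p.zshim_moment
                   for p in feasible_sets(default_grid(), standard_protocol)}
        assert moments == {-1.0, -0.5, 0.0, 0.5, 1.0}

    def test_reference_first(self, standard_protocol):
        sets = feasible_sets(default_grid(), standard_protocol)
        assert sets[0] == REFERENCE_PARAMS

    def test_grid_without_reference_rejected(self, standard_protocol):
        grid = ParameterGrid(zshim_values=(0.0,), tilt_values=(0.0,),
                             polarities=(Polarity.NEGATIVE, Polarity.POSITIVE))
        bad = dataclasses.replace(grid)
        object.__setattr__(bad, "polarities", (Polarity.NEGATIVE,))
        with pytest.raises(ValueError, match="reference"):
            feasible_sets(bad, standard_protocol)


class TestEvaluateGrid:
    def test_single_point_matches_direct_call(self, random_gradfield,
                                              standard_protocol):
        grid = build_grid(zshim=(0, 0, 1), tilt=(0, 0, 1),
                          polarities=("positive",))
        [(params, bs)] = list(evaluate_grid(random_gradfield,
                                            standard_protocol, grid))
        assert params == REFERENCE_PARAMS
        np.testing.assert_array_equal(
            bs, bs_volume(random_gradfield, standard_protocol, params))

    def test_zero_gradient_volume_only_shim_matters(self, standard_protocol):
        zeros = np.zeros((4, 4, 4))
        gf = gradfield_from_arrays(zeros, zeros, zeros)
        seen = {}
        for params, bs in evaluate_grid(gf, standard_protocol, SMALL_GRID):
            val = float(bs[0, 0, 0])
            seen.setdefault(params.zshim_moment, set()).add(round(val, 15))
        for vals in seen.values():  # same BS for every tilt/polarity
            assert len(vals) == 1

    def test_deterministic_order(self, random_gradfield, standard_protocol):
        order1 = [p for p, _ in evaluate_grid(random_gradfield,
                                              standard_protocol, SMALL_GRID)]
        order2 = [p for p, _ in evaluate_grid(random_gradfield,
                                              standard_protocol, SMALL_GRID)]
        assert order1 == order2
        assert order1 == sorted(order1, key=tie_key)


class TestOptimizeVoxelwise:
    def test_zero_gradient_voxel_prefers_reference(self, standard_protocol):
        zeros = np.zeros((2, 2, 2))
        res = optimize_voxelwise(gradfield_from_arrays(zeros, zeros, zeros),
                                 standard_protocol, SMALL_GRID)
        assert np.all(res.zshim_map == 0.0)
        assert np.all(res.tilt_map == 0.0)
        assert np.all(res.polarity_map == 1)
        np.testing.assert_allclose(res.gain_map, 0.0, atol=1e-12)

    def test_closed_form_zshim_recovery(self, standard_protocol):
        # optimum of the through-plane term is at M = -G_SL * TE0; pick
        # G_SL so the analytic optimum is exactly on-grid
        m_target = 1.0  # mT/m*ms
        g_sl = -m_target * constants.MT_PER_M_MS / standard_protocol.te0 \
            / constants.UT_PER_M  # = -33.33 uT/m
        zeros = np.zeros((1, 1, 1))
        gf = gradfield_from_arrays(zeros, zeros, np.full((1, 1, 1), g_sl))
        res = optimize_voxelwise(gf, standard_protocol, default_grid())
        assert res.zshim_map[0, 0, 0] == pytest.approx(m_target, abs=0.25)

    @pytest.mark.parametrize("orientation",
                             ["transverse", "sagittal", "coronal"])
    def test_matches_bruteforce_oracle(self, rng, orientation):
        proto = get_preset("standard", orientation=orientation)
        shape = (4, 4, 4)
        gx, gy, gz = rng.uniform(-90, 90, size=(3, *shape))
        res = optimize_voxelwise(gradfield_from_arrays(gx, gy, gz), proto,
                                 SMALL_GRID)
        for idx in np.ndindex(shape):
            (z, t, pol), bs = oracle.optimize_voxel_oracle(
                gx[idx], gy[idx], gz[idx], proto, SMALL_GRID,
                DEFAULT_CONFIG)
            assert res.zshim_map[idx] == z, idx
            assert res.tilt_map[idx] == t, idx
            assert res.polarity_map[idx] == (1 if pol == "positive" else -1)
            assert res.bs_map[idx] == pytest.approx(bs, rel=1e-12)

    def test_mirrored_field_flips_sagittal_zshim(self, rng):
        # sagittal slices have SL = X: mirroring the field left-right flips
        # G_SL and therefore the optimal z-shim sign
        proto = get_preset("standard", orientation="sagittal")
        gx = rng.uniform(-60, 60, size=(6, 4, 4))
        gy = rng.uniform(-60, 60, size=(6, 4, 4))
        gz = rng.uniform(-60, 60, size=(6, 4, 4))
        res = optimize_voxelwise(gradfield_from_arrays(gx, gy, gz), proto,
                                 SMALL_GRID)
        mirrored = optimize_voxelwise(
            gradfield_from_arrays(-gx[::-1], gy[::-1], gz[::-1]), proto,
            SMALL_GRID)
        np.testing.assert_allclose(mirrored.zshim_map[::-1], -res.zshim_map)
        np.testing.assert_allclose(mirrored.tilt_map[::-1], res.tilt_map)

    def test_nested_grid_monotonicity(self, rng, standard_protocol):
        gx, gy, gz = rng.uniform(-80, 80, size=(3, 3, 3, 3))
        gf = gradfield_from_arrays(gx, gy, gz)
        coarse = optimize_voxelwise(gf, standard_protocol,
                                    build_grid(zshim=(-2, 2, 1),
                                               tilt=(-30, 30, 30)))
        fine = optimize_voxelwise(gf, standard_protocol,
                                  build_grid(zshim=(-2, 2, 0.5),
                                             tilt=(-30, 30, 15)))
        assert np.all(fine.bs_map >= coarse.bs_map - 1e-15)

    def test_display_mask(self, random_gradfield, standard_protocol):
        res = optimize_voxelwise(random_gradfield, standard_protocol,
                                 SMALL_GRID)
        masked = res.masked_gain_map(20.0)
        below = res.gain_map < 20.0
        assert np.isnan(masked[below]).all()


class TestOptimizeROI:
    def test_single_voxel_roi_equals_voxelwise(self, rng,
                                               standard_protocol):
        gx, gy, gz = rng.uniform(-90, 90, size=(3, 3, 3, 3))
        gf = gradfield_from_arrays(gx, gy, gz)
        labels = np.zeros((3, 3, 3), int)
        labels[1, 1, 1] = 1
        rois = ROISet(labels=labels, names={1: "probe"})
        roi_res = optimize_roi(gf, standard_protocol, SMALL_GRID, rois)
        vox_res = optimize_voxelwise(gf, standard_protocol, SMALL_GRID)
        row = roi_res.roi_table.iloc[0]
        assert row["zshim"] == vox_res.zshim_map[1, 1, 1]
        assert row["tilt"] == vox_res.tilt_map[1, 1, 1]
        assert row["mean_bs"] == pytest.approx(vox_res.bs_map[1, 1, 1])

    def test_opposed_gsl_pair_prefers_zero_shim(self, standard_protocol):
        gz = np.array([[[40.0]], [[-40.0]]])
        zeros = np.zeros_like(gz)
        gf = gradfield_from_arrays(zeros, zeros, gz)
        rois = ROISet(labels=np.ones_like(gz, int), names={1: "pair"})
        res = optimize_roi(gf, standard_protocol, SMALL_GRID, rois)
        assert abs(res.roi_table.iloc[0]["zshim"]) <= 0.5

    def test_matches_bruteforce_oracle(self, rng, standard_protocol):
        shape = (4, 4, 2)
        gx, gy, gz = rng.uniform(-90, 90, size=(3, *shape))
        labels = (rng.uniform(size=shape) < 0.4).astype(int)
        labels[0, 0, 0] = 1
        gf = gradfield_from_arrays(gx, gy, gz)
        rois = ROISet(labels=labels, names={1: "blob"})
        res = optimize_roi(gf, standard_protocol, SMALL_GRID, rois)
        voxels = [(gx[i], gy[i], gz[i])
                  for i in zip(*np.nonzero(labels))]
        (z, t, pol), mean = oracle.optimize_roi_oracle(
            voxels, standard_protocol, SMALL_GRID, DEFAULT_CONFIG)
        row = res.roi_table.iloc[0]
        assert row["zshim"] == z
        assert row["tilt"] == t
        assert row["polarity"] == pol
        assert row["mean_bs"] == pytest.approx(mean, rel=1e-12)
        assert row["gain"] >= 0.0

    def test_empty_roi_reported_missing(self, standard_protocol):
        zeros = np.zeros((2, 2, 2))
        mask = np.zeros((2, 2, 2), bool)
        mask[0] = True
        gf = gradfield_from_arrays(zeros, zeros, zeros, mask=mask)
        labels = np.zeros((2, 2, 2), int)
        labels[1, 0, 0] = 2  # entirely outside the field mask
        res = optimize_roi(gf, standard_protocol, SMALL_GRID,
                           ROISet(labels=labels, names={2: "outside"}))
        row = res.roi_table.iloc[0]
        assert np.isnan(row["mean_bs"]) and row["n_voxels"] == 0

    def test_gain_surfaces_cover_grid(self, random_gradfield,
                                      standard_protocol):
        labels = np.zeros(random_gradfield.shape, int)
        labels[2:5, 2:5, 2:5] = 1
        res = optimize_roi(random_gradfield, standard_protocol, SMALL_GRID,
                           ROISet(labels=labels, names={1: "cube"}))
        surf = res.gain_surfaces[("cube", "positive")]
        assert surf.shape == (len(SMALL_GRID.tilt_values),
                              len(SMALL_GRID.zshim_values))
        # infeasible shim columns stay missing, feasible ones are filled
        assert surf[0.0].notna().all()
        assert surf[2.0].isna().all()
        assert surf.loc[0.0, 0.0] == pytest.approx(0.0)


class TestCrossROIImpact:
    def _setup(self, rng, protocol):
        shape = (6, 4, 4)
        gx, gy, gz = rng.uniform(-80, 80, size=(3, *shape))
        gf = gradfield_from_arrays(gx, gy, gz)
        labels = np.zeros(shape, int)
        labels[:2] = 1
        labels[4:] = 2
        rois = ROISet(labels=labels, names={1: "front", 2: "back"})
        res = optimize_roi(gf, protocol, SMALL_GRID, rois)
        return gf, rois, res

    def test_diagonal_nonnegative(self, rng, standard_protocol):
        gf, rois, res = self._setup(rng, standard_protocol)
        impact = cross_roi_impact(gf, standard_protocol, res, rois)
        for name in ("front", "back"):
            assert impact.loc[name, name] >= 0.0

    def test_wellshimmed_column_respects_constraint(self, rng,
                                                    standard_protocol):
        gf, rois, res = self._setup(rng, standard_protocol)
        impact = cross_roi_impact(gf, standard_protocol, res, rois)
        # loss <= 15 % translates to a symmetric gain >= 200*(-.15)/1.85
        bound = 200.0 * (0.85 - 1.0) / 1.85
        assert (impact["Well-Shimmed"] >= bound - 1e-9).all()
        assert (impact["Well-Shimmed"] >= -15.0 - 1e-9).all()

    def test_antagonistic_rois_negative_offdiagonal(self, standard_protocol):
        # two ROIs needing opposite z-shims: optimizing one hurts the other
        gz = np.zeros((2, 1, 1))
        gz[0], gz[1] = 60.0, -60.0
        zeros = np.zeros_like(gz)
        gf = gradfield_from_arrays(zeros, zeros, gz)
        labels = np.array([[[1]], [[2]]])
        rois = ROISet(labels=labels, names={1: "up", 2: "down"})
        res = optimize_roi(gf, standard_protocol, SMALL_GRID, rois)
        impact = cross_roi_impact(gf, standard_protocol, res, rois)
        assert impact.loc["up", "down"] < 0
        assert impact.loc["down", "up"] < 0


class TestPerSubjectOptima:
    def test_identical_subjects_degenerate(self, rng, standard_protocol):
        gx, gy, gz = rng.uniform(-60, 60, size=(3, 4, 4, 4))
        gf = gradfield_from_arrays(gx, gy, gz)
        labels = np.zeros((4, 4, 4), int)
        labels[1:3] = 1
        rois = ROISet(labels=labels, names={1: "roi"})
        out = per_subject_optima([gf, gf, gf], standard_protocol,
                                 SMALL_GRID, rois)
        assert out.gain_summary.loc["roi", "gain_sd"] == pytest.approx(0.0)
        z_hist = out.zshim_histograms.loc["roi"]
        assert (z_hist > 0).sum() == 1 and z_hist.sum() == 3

    def test_perturbed_subjects_cluster(self, rng, standard_protocol):
        base = rng.uniform(-60, 60, size=(3, 4, 4, 4))
        subjects = []
        for _ in range(5):
            pert = base + rng.normal(0, 1.0, size=base.shape)
            subjects.append(gradfield_from_arrays(*pert))
        labels = np.zeros((4, 4, 4), int)
        labels[1:3] = 1
        rois = ROISet(labels=labels, names={1: "roi"})
        out = per_subject_optima(subjects, standard_protocol, SMALL_GRID,
                                 rois)
        z_hist = out.zshim_histograms.loc["roi"]
        support = z_hist[z_hist > 0].index.to_numpy(dtype=float)
        assert support.max() - support.min() <= 1.0  # within 2 grid steps

    def test_requires_subjects(self, standard_protocol):
        with pytest.raises(ValueError):
            per_subject_optima([], standard_protocol, SMALL_GRID,
                               ROISet(labels=np.zeros((2, 2, 2), int),
                                      names={}))


class TestConstraintInvariant:
    def test_every_reported_set_is_feasible(self, rng, standard_protocol):
        gx, gy, gz = rng.uniform(-100, 100, size=(3, 5, 5, 5))
        gf = gradfield_from_arrays(gx, gy, gz)
        res = optimize_voxelwise(gf, standard_protocol, default_grid())
        for z in np.unique(res.zshim_map):
            loss = wellshimmed_loss(AdjustableParams(z, 0, "positive"),
                                    standard_protocol)
            assert loss <= MAX_WELLSHIMMED_LOSS + 1e-12
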