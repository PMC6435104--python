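"""Exhaustive grid search maximizing BOLD sensitivity voxel-wise and per
region of interest, under the hard well-shimmed-loss boundary condition.

Parameter sets whose BS loss in gradient-free tissue exceeds the limit
(default 15 %) are excluded a priori: the constraint depends only on the
z-shim moment, never on the voxel, so filtering before the argmax is
equivalent to falling back to the next-best feasible set.

Ties are broken deterministically: smallest |z-shim|, then positive z-shim,
then smallest |tilt|, then positive tilt, then positive PE polarity. The
convention is ours — the reference point therefore always wins exact ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .bs_core import (BSModelConfig, DEFAULT_CONFIG, bs_gain, voxel_bs,
                      wellshimmed_loss)
from .field_io import GradientField, average_maps
from .geometry import canonical_frame, project_gradient_volumes, tilt_frame
from .protocol import (AdjustableParams, EPIProtocol, ParameterGrid,
                       Polarity, REFERENCE_PARAMS)

__all__ = [
    "ROISet", "OptimizationResult", "MAX_WELLSHIMMED_LOSS", "tie_key",
    "feasible_sets", "evaluate_grid", "bs_volume", "optimize_voxelwise",
    "optimize_roi", "cross_roi_impact", "per_subject_optima",
    "PerSubjectResult",
]

MAX_WELLSHIMMED_LOSS = 0.15


@dataclass
class ROISet:
    """Integer label volume plus label -> name table."""

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if np.issubdtype(self.labels.dtype, np.floating):
            self.labels = self.labels.astype(np.int32)
        if (self.labels < 0).any():
            raise ValueError("ROI labels must be non-negative")
        self.names = {int(k): str(v) for k, v in dict(self.names).items()}
        present = set(np.unique(self.labels).tolist())
        missing = [k for k in self.names if k not in present and k != 0]
        if missing:
            raise ValueError(f"named labels absent from volume: {missing}")

    def masks(self) -> Iterator[tuple[int, str, np.ndarray]]:
        for label in sorted(self.names):
            if label == 0:
                continue
            yield label, self.names[label], self.labels == label


@dataclass
class OptimizationResult:
    """Outputs of the voxel-wise and/or ROI grid search."""

    protocol: EPIProtocol
    grid: ParameterGrid
    # voxel-wise part
    zshim_map: np.ndarray | None = None
    tilt_map: np.ndarray | None = None
    polarity_map: np.ndarray | None = None  # +1 positive, -1 negative
    bs_map: np.ndarray | None = None
    bs_ref_map: np.ndarray | None = None
    gain_map: np.ndarray | None = None
    # ROI part
    roi_table: pd.DataFrame | None = None
    gain_surfaces: dict | None = None  # (roi name, polarity) -> DataFrame
    impact_matrix: pd.DataFrame | None = None

    def masked_gain_map(self, min_gain: float = 20.0) -> np.ndarray:
        """Gain map with voxels below ``min_gain`` percent set to NaN
        (display convention for optimized-parameter maps)."""
        if self.gain_map is None:
            raise ValueError("voxel-wise gain map not computed")
        return np.where(self.gain_map >= min_gain, self.gain_map, np.nan)


def tie_key(params: AdjustableParams):
    """Deterministic preference order for equal-BS parameter sets."""
    return (abs(params.zshim_moment), params.zshim_moment < 0,
            abs(params.tilt_deg), params.tilt_deg < 0,
            params.pe_polarity is not Polarity.POSITIVE)


def feasible_sets(grid: ParameterGrid, protocol: EPIProtocol,
                  config: BSModelConfig = DEFAULT_CONFIG,
                  max_loss: float = MAX_WELLSHIMMED_LOSS,
                  ) -> list[AdjustableParams]:
    """Grid points satisfying the well-shimmed-loss constraint, ordered by
    tie preference (reference point first)."""
    sets = [p for p in grid
            if wellshimmed_loss(p, protocol, config) <= max_loss]
    sets.sort(key=tie_key)
    if not sets or sets[0] != REFERENCE_PARAMS:
        raise ValueError("grid does not contain the reference point "
                         "(0 shim, 0 tilt, positive polarity)")
    return sets


class _ProjectionCache:
    """Per-tilt slice-frame projections of the gradient component volumes."""

    def __init__(self, gradfield: GradientField, protocol: EPIProtocol):
        self._gf = gradfield
        self._base = canonical_frame(protocol.orientation)
        self._cache: dict[float, tuple] = {}

    def __call__(self, tilt_deg: float):
        if tilt_deg not in self._cache:
            frame = tilt_frame(self._base, tilt_deg)
            self._cache[tilt_deg] = project_gradient_volumes(
                self._gf.gx, self._gf.gy, self._gf.gz, frame)
        return self._cache[tilt_deg]


def bs_volume(gradfield: GradientField, protocol: EPIProtocol,
              params: AdjustableParams,
              config: BSModelConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Relative-BS volume for one parameter set (NaN outside the mask)."""
    frame = tilt_frame(canonical_frame(protocol.orientation), params.tilt_deg)
    g_ro, g_pe, g_sl = project_gradient_volumes(
        gradfield.gx, gradfield.gy, gradfield.gz, frame)
    bs = voxel_bs(g_ro, g_pe, g_sl, protocol, params, config).bs_rel
    if gradfield.mask is not None:
        bs = np.where(gradfield.mask, bs, np.nan)
    return bs


def evaluate_grid(gradfield: GradientField, protocol: EPIProtocol,
                  grid: ParameterGrid,
                  config: BSModelConfig = DEFAULT_CONFIG,
                  feasible_only: bool = True,
                  ) -> Iterator[tuple[AdjustableParams, np.ndarray]]:
    """Lazily yield ``(params, bs_volume)`` for every grid point.

    Volumes are produced one parameter set at a time (deterministic,
    tie-preference order when ``feasible_only``), so memory stays bounded
    regardless of grid size; callers needing the full stack can collect it
    explicitly.
    """
    if feasible_only:
        sets = feasible_sets(grid, protocol, config)
    else:
        sets = sorted(grid, key=tie_key)
    project = _ProjectionCache(gradfield, protocol)
    for params in sets:
        g_ro, g_pe, g_sl = project(params.tilt_deg)
        bs = voxel_bs(g_ro, g_pe, g_sl, protocol, params, config).bs_rel
        if gradfield.mask is not None:
            bs = np.where(gradfield.mask, bs, np.nan)
        yield params, bs


def optimize_voxelwise(gradfield: GradientField, protocol: EPIProtocol,
                       grid: ParameterGrid,
                       config: BSModelConfig = DEFAULT_CONFIG,
                       max_loss: float = MAX_WELLSHIMMED_LOSS,
                       ) -> OptimizationResult:
    """Per-voxel argmax of BS over all feasible parameter sets."""
    best = None
    zmap = tmap = pmap = None
    ref_bs = None
    for params, bs in evaluate_grid(gradfield, protocol, grid, config):
        if best is None:
            shape = bs.shape
            best = np.full(shape, -np.inf)
            zmap = np.zeros(shape)
            tmap = np.zeros(shape)
            pmap = np.ones(shape, dtype=np.int8)
        if params == REFERENCE_PARAMS:
            ref_bs = bs
        upd = bs > best  # iteration order implements the tie preference
        best[upd] = bs[upd]
        zmap[upd] = params.zshim_moment
        tmap[upd] = params.tilt_deg
        pmap[upd] = params.pe_polarity.sign
    assert ref_bs is not None
    invalid = ~np.isfinite(ref_bs)
    for arr, fill in ((best, np.nan), (zmap, np.nan), (tmap, np.nan)):
        arr[invalid] = fill
    pmap = np.where(invalid, 0, pmap)
    gain = bs_gain(best, ref_bs)
    return OptimizationResult(protocol=protocol, grid=grid, zshim_map=zmap,
                              tilt_map=tmap, polarity_map=pmap, bs_map=best,
                              bs_ref_map=ref_bs, gain_map=gain)


def _roi_means(bs: np.ndarray, roi_masks: Sequence[np.ndarray]) -> list[float]:
    out = []
    for m in roi_masks:
        vals = bs[m]
        vals = vals[np.isfinite(vals)]
        out.append(float(vals.mean()) if vals.size else np.nan)
    return out


def optimize_roi(gradfield: GradientField, protocol: EPIProtocol,
                 grid: ParameterGrid, rois: ROISet,
                 config: BSModelConfig = DEFAULT_CONFIG,
                 surfaces: bool = True) -> OptimizationResult:
    """Per-ROI argmax of mean BS across the ROI's voxels.

    Empty ROIs (no voxels inside the gradient-field mask) produce a missing
    row rather than an error. Gain surfaces over (tilt, z-shim) are exported
    per ROI and polarity when ``surfaces`` is requested.
    """
    roi_list = list(rois.masks())
    masks = [m for _, _, m in roi_list]
    records = []  # (params, [mean bs per roi])
    ref_means = None
    for params, bs in evaluate_grid(gradfield, protocol, grid, config):
        means = _roi_means(bs, masks)
        records.append((params, means))
        if params == REFERENCE_PARAMS:
            ref_means = means
    assert ref_means is not None

    rows = []
    surf: dict = {} if surfaces else None
    for i, (label, name, mask) in enumerate(roi_list):
        if not np.isfinite(ref_means[i]):
            rows.append(dict(label=label, roi=name, zshim=np.nan,
                             tilt=np.nan, polarity="", mean_bs=np.nan,
                             gain=np.nan, n_voxels=0))
            continue
        best_params, best_mean = None, -np.inf
        for params, means in records:  # tie-preference order
            if means[i] > best_mean:
                best_params, best_mean = params, means[i]
        rows.append(dict(
            label=label, roi=name, zshim=best_params.zshim_moment,
            tilt=best_params.tilt_deg, polarity=best_params.pe_polarity.value,
            mean_bs=best_mean, gain=bs_gain(best_mean, ref_means[i]),
            n_voxels=int(mask.sum())))
        if surfaces:
            for pol in grid.polarities:
                tab = pd.DataFrame(
                    index=pd.Index(grid.tilt_values, name="tilt_deg"),
                    columns=pd.Index(grid.zshim_values, name="zshim"),
                    dtype=float)
                for params, means in records:
                    if params.pe_polarity is pol:
                        tab.loc[params.tilt_deg, params.zshim_moment] = \
                            bs_gain(means[i], ref_means[i])
                surf[(name, pol.value)] = tab
    table = pd.DataFrame(rows)
    return OptimizationResult(protocol=protocol, grid=grid, roi_table=table,
                              gain_surfaces=surf)


def cross_roi_impact(gradfield: GradientField, protocol: EPIProtocol,
                     roi_result: OptimizationResult, rois: ROISet,
                     config: BSModelConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Gain matrix: entry (i, j) is the BS gain in ROI j when scanning with
    ROI i's optimal parameter set.

    Gains are computed from ROI-mean BS (the quantity the ROI optimization
    maximizes), so diagonal entries are >= 0 by construction. Whole-Brain
    and Well-Shimmed pseudo-ROIs are appended: Well-Shimmed uses the
    zero-gradient BS, whose loss is bounded by the 15 % constraint.
    """
    roi_list = list(rois.masks())
    names = [name for _, name, _ in roi_list]
    table = roi_result.roi_table.set_index("roi")

    wb_mask = gradfield.mask if gradfield.mask is not None \
        else np.ones(gradfield.shape, bool)
    col_names = names + ["Whole-Brain", "Well-Shimmed"]

    def means_for(params: AdjustableParams):
        bs = bs_volume(gradfield, protocol, params, config)
        m = _roi_means(bs, [mask for _, _, mask in roi_list] + [wb_mask])
        ws = float(voxel_bs(0.0, 0.0, 0.0, protocol, params, config).bs_rel)
        return m + [ws]

    ref_means = means_for(REFERENCE_PARAMS)
    rows = {}
    for name in names:
        row = table.loc[name]
        if not np.isfinite(row["mean_bs"]):
            rows[name] = [np.nan] * len(col_names)
            continue
        params = AdjustableParams(row["zshim"], row["tilt"], row["polarity"])
        rows[name] = [bs_gain(m, r)
                      for m, r in zip(means_for(params), ref_means)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=col_names)


@dataclass
class PerSubjectResult:
    """Cohort summary: optimum histograms and gain at the group optimum."""

    group_table: pd.DataFrame
    tilt_histograms: pd.DataFrame   # rows (roi, polarity), cols tilt values
    zshim_histograms: pd.DataFrame  # rows roi, cols zshim values
    subject_gains: pd.DataFrame     # rows roi, cols subject index
    gain_summary: pd.DataFrame      # roi, gain_mean, gain_sd


def per_subject_optima(gradfields: Sequence[GradientField],
                       protocol: EPIProtocol, grid: ParameterGrid,
                       rois: ROISet,
                       config: BSModelConfig = DEFAULT_CONFIG,
                       ) -> PerSubjectResult:
    """Optimize per subject and report optimum histograms plus the per-ROI
    mean +- sd of subject gains at the group-optimal parameter set.

    The group optimum per ROI is obtained from the voxel-wise average of the
    subjects' gradient fields (the co-registered-average pathway); subject
    gains compare each subject's ROI-mean BS at that set against the
    subject's own reference.
    """
    gradfields = list(gradfields)
    if not gradfields:
        raise ValueError("need at least one subject")
    group = average_maps(gradfields) if len(gradfields) > 1 else gradfields[0]
    group_res = optimize_roi(group, protocol, grid, rois, config,
                             surfaces=False)
    group_table = group_res.roi_table.set_index("roi")

    roi_list = list(rois.masks())
    names = [name for _, name, _ in roi_list]
    tilt_rows = {(n, p.value): {t: 0 for t in grid.tilt_values}
                 for n in names for p in grid.polarities}
    z_rows = {n: {z: 0 for z in grid.zshim_values} for n in names}
    subj_gain = {n: [] for n in names}

    for gf in gradfields:
        res = optimize_roi(gf, protocol, grid, rois, config, surfaces=False)
        tab = res.roi_table.set_index("roi")
        for name in names:
            row = tab.loc[name]
            if np.isfinite(row["mean_bs"]):
                tilt_rows[(name, row["polarity"])][row["tilt"]] += 1
                z_rows[name][row["zshim"]] += 1
            grow = group_table.loc[name]
            if not np.isfinite(grow["mean_bs"]):
                subj_gain[name].append(np.nan)
                continue
            gparams = AdjustableParams(grow["zshim"], grow["tilt"],
                                       grow["polarity"])
            bs = bs_volume(gf, protocol, gparams, config)
            ref = bs_volume(gf, protocol, REFERENCE_PARAMS, config)
            mask = next(m for lbl, n2, m in rois.masks() if n2 == name)
            mean_bs = _roi_means(bs, [mask])[0]
            mean_ref = _roi_means(ref, [mask])[0]
            subj_gain[name].append(bs_gain(mean_bs, mean_ref))

    tilt_hist = pd.DataFrame.from_dict(tilt_rows, orient="index")
    tilt_hist.index = pd.MultiIndex.from_tuples(tilt_hist.index,
                                                names=["roi", "polarity"])
    z_hist = pd.DataFrame.from_dict(z_rows, orient="index")
    z_hist.index.name = "roi"
    gains = pd.DataFrame.from_dict(subj_gain, orient="index")
    gains.index.name = "roi"
    summary = pd.DataFrame({
        "gain_mean": gains.mean(axis=1, skipna=True),
        "gain_sd": gains.std(axis=1, ddof=1, skipna=True),
    })
    return PerSubjectResult(group_table=group_res.roi_table,
                            tilt_histograms=tilt_hist,
                            zshim_histograms=z_hist,
                            subject_gains=gains, gain_summary=summary)
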