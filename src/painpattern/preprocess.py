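"""Per-run preprocessing: motion regression, detrending/standardization,
smoothing, peak-volume sample extraction, trial averaging, ROI-wise signal
normalization, first-level GLM betas, and peri-stimulus time courses.

The canonical pipeline order (event-related decoding) is: motion
regression -> linear detrend + z-score -> peak-volume extraction ->
averaging per modality/run/subject -> optional ROI normalization. Both
orders of the first two steps are supported; motion-first is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .hrf import double_gamma_hrf
from .images import VolumeSeries
from .masks import Mask

__all__ = [
    "PatternSample",
    "detrend_zscore", "regress_out_motion", "summarize_motion",
    "gaussian_smooth", "extract_peak_samples", "average_samples",
    "roi_normalize", "glm_betas", "extract_timecourses",
    "FD_ROTATION_RADIUS_MM",
]

FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class PatternSample:
    """One pattern vector over the voxels of an ROI mask (fixed C-ordering),
    with labels identifying its provenance."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self):
        return self.values.size


def _flat(series: VolumeSeries) -> np.ndarray:
    """(n_voxels, n_volumes) view of a series."""
    return series.data.reshape(-1, series.n_volumes)


def detrend_zscore(series: VolumeSeries) -> VolumeSeries:
    """Remove each voxel's least-squares linear trend over time, then divide
    by the residual standard deviation. Constant (zero-variance) voxels come
    out all-zero so downstream algebra never sees non-finite values."""
    if series.n_volumes < 3:
        raise ValueError("need at least 3 volumes to detrend")
    y = _flat(series)
    t = np.arange(series.n_volumes, dtype=float)
    t = (t - t.mean())
    denom = (t ** 2).sum()
    slope = (y @ t) / denom
    resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * t[None, :]
    sd = resid.std(axis=1, ddof=0)
    out = np.zeros_like(resid)
    ok = sd > 0
    out[ok] = resid[ok] / sd[ok, None]
    return VolumeSeries(out.reshape(series.data.shape), series.affine, series.tr)


def regress_out_motion(series: VolumeSeries, motion: np.ndarray) -> VolumeSeries:
    """Residualize every voxel on [intercept + 6 motion columns].

    Collinear motion columns are dropped with a warning rather than letting
    the fit blow up.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != series.n_volumes:
        raise ValueError("motion table length does not match n_volumes")
    X = np.column_stack([np.ones(series.n_volumes), motion])
    # drop collinear columns (beyond the intercept) via rank-revealing QR
    q, r, piv = _qr_pivot(X)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(abs(r[0, 0]), 1)).sum())
    if rank < X.shape[1]:
        keep = sorted(piv[:rank])
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        warnings.warn(f"dropping collinear motion design columns {dropped}")
        X = X[:, keep]
    y = _flat(series)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ beta
    return VolumeSeries(resid.T.reshape(series.data.shape),
                        series.affine, series.tr)


def _qr_pivot(X):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def framewise_displacement(motion: np.ndarray,
                           rotation_radius: float = FD_ROTATION_RADIUS_MM
                           ) -> np.ndarray:
    """Power-style framewise displacement: sum of absolute backward
    differences of the 3 translations (mm) and the 3 rotations converted to
    arc length on a ``rotation_radius`` mm sphere. First volume gets 0."""
    motion = np.asarray(motion, dtype=float)
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def summarize_motion(motion: np.ndarray, events: pd.DataFrame, modality: str,
                     tr: float, window_volumes: int = 3) -> float:
    """Mean framewise displacement (mm) over the volumes within the
    stimulation windows of one modality (onset volume plus the following
    ``window_volumes - 1`` volumes)."""
    ev = events[events["modality"] == modality]
    if len(ev) == 0:
        raise ValueError(f"no events of modality {modality!r}")
    fd = framewise_displacement(motion)
    idx = []
    for onset in ev["onset_s"].to_numpy():
        start = int(np.floor(onset / tr))
        idx.extend(range(start, min(start + window_volumes, len(fd))))
    return float(fd[sorted(set(idx))].mean())


def gaussian_smooth(series: VolumeSeries, fwhm: float) -> VolumeSeries:
    """Separable 3D Gaussian smoothing with the kernel width given in world
    mm (FWHM); each volume is smoothed independently. ``fwhm=0`` is the
    identity. Reflective boundaries preserve the volume mean."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return series
    vox = np.abs(np.diag(series.affine[:3, :3]))
    sigma_vox = (fwhm / 2.3548) / vox
    out = ndimage.gaussian_filter(
        series.data, sigma=(*sigma_vox, 0.0), mode="reflect")
    return VolumeSeries(out, series.affine, series.tr)


def peak_volume_index(onset: float, tr: float, peak_offset: int) -> int:
    """Volume ``i`` covers [i*tr, (i+1)*tr); the k-th volume after onset is
    floor(onset/tr) + k. A tiny epsilon guards onsets that land exactly on
    a volume boundary against floating-point round-off."""
    return int(np.floor(onset / tr + 1e-9)) + peak_offset


def extract_peak_samples(series: VolumeSeries, events: pd.DataFrame,
                         mask: Mask, peak_offset: int) -> list:
    """One PatternSample per event, taken from the volume ``peak_offset``
    volumes after stimulus onset, restricted to the mask. Events whose peak
    volume falls outside the run are skipped with a warning."""
    if mask.grid_shape != series.grid_shape:
        raise ValueError("mask grid does not match series grid")
    idx = mask.indices()
    samples = []
    for _, row in events.iterrows():
        v = peak_volume_index(row["onset_s"], series.tr, peak_offset)
        if not (0 <= v < series.n_volumes):
            warnings.warn(
                f"event at {row['onset_s']:.1f}s: peak volume {v} outside run")
            continue
        meta = {k: row[k] for k in row.index}
        meta["peak_volume"] = v
        samples.append(PatternSample(series.data[idx + (v,)], meta=meta))
    return samples


def average_samples(samples: list, by: tuple = ("modality",)) -> list:
    """Element-wise mean of samples grouped by the given meta keys; shared
    meta entries are propagated, conflicting ones dropped."""
    if not samples:
        return []
    n = len(samples[0])
    if any(len(s) != n for s in samples):
        raise ValueError("samples have inconsistent lengths (mixed masks?)")
    groups: dict = {}
    for s in samples:
        key = tuple(s.meta.get(k) for k in by)
        groups.setdefault(key, []).append(s)
    out = []
    for key, members in groups.items():
        vals = np.mean([m.values for m in members], axis=0)
        meta = dict(zip(by, key))
        # propagate meta fields constant within the group
        for k in members[0].meta:
            if k in meta:
                continue
            uniq = {repr(m.meta.get(k)) for m in members}
            if len(uniq) == 1:
                meta[k] = members[0].meta[k]
        meta["n_averaged"] = len(members)
        out.append(PatternSample(vals, meta=meta,
                                 normalized=all(m.normalized for m in members)))
    return out


def roi_normalize(sample: PatternSample) -> PatternSample:
    """Center and scale a pattern across ROI voxels (mean 0, SD 1), removing
    any overall amplitude difference between conditions."""
    v = sample.values
    if v.size < 2:
        raise ValueError("need at least 2 voxels to normalize")
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant sample cannot be normalized")
    return PatternSample((v - v.mean()) / sd, meta=dict(sample.meta),
                         normalized=True)


# ---------------------------------------------------------------------------
# first-level GLM
# ---------------------------------------------------------------------------

def _condition_regressor(t: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    return double_gamma_hrf(t[None, :] - onsets[:, None]).sum(axis=0)


def glm_betas(series: VolumeSeries, events: pd.DataFrame,
              motion: np.ndarray | None = None,
              condition_key: str = "modality") -> dict:
    """Voxelwise OLS betas per condition.

    Design: per-condition HRF-convolved stick functions, their temporal
    derivatives, 6 motion columns, an intercept and a linear drift. Returns
    ``{condition: 3D beta map}``. Raises on a rank-deficient design, naming
    the collinear columns.
    """
    t = np.arange(series.n_volumes) * series.tr
    conditions = list(dict.fromkeys(events[condition_key]))
    cols, names = [], []
    dt = series.tr
    for c in conditions:
        onsets = events.loc[events[condition_key] == c, "onset_s"].to_numpy()
        reg = _condition_regressor(t, onsets)
        cols.append(reg)
        names.append(f"beta:{c}")
        cols.append(np.gradient(reg, dt))
        names.append(f"dbeta:{c}")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        for m in range(motion.shape[1]):
            cols.append(motion[:, m])
            names.append(f"motion:{m}")
    cols.append(np.ones(series.n_volumes))
    names.append("intercept")
    drift = t - t.mean()
    cols.append(drift / max(np.abs(drift).max(), 1.0))
    names.append("drift")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = _qr_pivot(X)
        bad = sorted(piv[rank:])
        raise ValueError("rank-deficient GLM design; collinear columns: "
                         + ", ".join(names[b] for b in bad))
    y = _flat(series)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    out = {}
    for c in conditions:
        b = beta[names.index(f"beta:{c}")]
        out[c] = b.reshape(series.grid_shape)
    return out


def extract_timecourses(series: VolumeSeries, events: pd.DataFrame,
                        roi: Mask, window: tuple = (-1, 5),
                        condition_key: str = "modality") -> pd.DataFrame:
    """Trial-averaged ROI-mean signal at each volume from ``window[0]`` to
    ``window[1]`` TRs relative to stimulus onset, per condition.

    Returns a tidy frame with columns condition, rel_volume, rel_time_s,
    mean, sd, n_trials. Events whose window leaves the run are excluded;
    raises if a condition retains no events.
    """
    lo, hi = int(window[0]), int(window[1])
    roi_idx = roi.indices()
    roi_mean = series.data[roi_idx].mean(axis=0)  # (n_volumes,)
    rows = []
    for c in dict.fromkeys(events[condition_key]):
        onsets = events.loc[events[condition_key] == c, "onset_s"].to_numpy()
        courses = []
        for onset in onsets:
            v0 = int(np.floor(onset / series.tr))
            if v0 + lo < 0 or v0 + hi >= series.n_volumes:
                continue
            courses.append(roi_mean[v0 + lo: v0 + hi + 1])
        if not courses:
            raise ValueError(f"no includable events for condition {c!r}")
        courses = np.asarray(courses)
        for off in range(lo, hi + 1):
            col = courses[:, off - lo]
            rows.append({"condition": c, "rel_volume": off,
                         "rel_time_s": off * series.tr,
                         "mean": col.mean(), "sd": col.std(ddof=0),
                         "n_trials": len(courses)})
    return pd.DataFrame(rows)
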