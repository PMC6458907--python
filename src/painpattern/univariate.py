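"""ROI-wise univariate amplitude comparisons with family-wise error control
by max-statistic sign-flip permutation.

For a family of ROIs (ten in the canonical analysis), per-subject condition
differences in ROI-mean signal are tested with paired t-tests; the corrected
p-value of each ROI is the proportion of sign-flip permutations whose
maximum |t| across the family reaches that ROI's observed |t|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .masks import Mask
from .preprocess import PatternSample

__all__ = ["roi_mean_signal", "roi_family_test", "ROIFamilyResult"]


def roi_mean_signal(sample: PatternSample, parent_mask: Mask, roi: Mask) -> float:
    """Mean of a pattern sample over the voxels of ``roi``.

    The sample is a vector over ``parent_mask``'s voxels (canonical
    ordering); ``roi`` must be a subset of the parent mask.
    """
    if not roi.issubset(parent_mask):
        raise ValueError("roi is not a subset of the sample's parent mask")
    parent_idx = np.column_stack(parent_mask.indices())
    roi_flags = roi.data[parent_idx[:, 0], parent_idx[:, 1], parent_idx[:, 2]]
    if not roi_flags.any():
        raise ValueError("roi has no voxels inside the parent mask")
    return float(sample.values[roi_flags].mean())


@dataclass
class ROIFamilyResult:
    table: pd.DataFrame       # roi, mean_a, sd_a, mean_b, sd_b, t, p_uncorrected, p_corrected
    n_perm: int
    exhaustive: bool
    excluded: list

    def to_dict(self) -> dict:
        return {"n_perm": self.n_perm, "exhaustive": self.exhaustive,
                "excluded": self.excluded,
                "rois": self.table.to_dict(orient="records")}


def roi_family_test(means_a: np.ndarray, means_b: np.ndarray,
                    roi_names=None, n_perm: int = 5000,
                    seed: int = 0) -> ROIFamilyResult:
    """Paired comparison of two conditions across a family of ROIs.

    ``means_a``/``means_b`` are (n_subjects, n_rois) arrays of per-subject
    ROI-mean signals. Corrected p-values use the max-|t| distribution over
    sign flips of the subject difference vectors: all 2^n flips are
    enumerated when that is no more than ``n_perm``, otherwise ``n_perm``
    random flips are drawn and the (k+1)/(n+1) estimator keeps p in (0, 1].
    Zero-variance ROIs are flagged, excluded from the max statistic, and
    reported with NaN p-values.
    """
    A = np.asarray(means_a, dtype=float)
    B = np.asarray(means_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("means_a and means_b must be matching 2D arrays")
    n_sub, n_roi = A.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if roi_names is None:
        roi_names = [f"roi{r}" for r in range(n_roi)]
    D = A - B
    sd = D.std(axis=0, ddof=1)
    # relative guard: catches constant differences up to float round-off
    scale = np.maximum(np.abs(D).max(axis=0), 1e-300)
    ok = sd > 1e-10 * scale
    excluded = [roi_names[r] for r in range(n_roi) if not ok[r]]

    def tstats(diff):
        return diff.mean(axis=0) / (diff.std(axis=0, ddof=1) / np.sqrt(n_sub))

    t_obs = np.full(n_roi, np.nan)
    t_obs[ok] = tstats(D[:, ok])
    p_unc = np.full(n_roi, np.nan)
    p_unc[ok] = 2 * stats.t.sf(np.abs(t_obs[ok]), df=n_sub - 1)

    exhaustive = 2 ** n_sub <= n_perm
    Dok = D[:, ok]
    if exhaustive:
        n_used = 2 ** n_sub
        signs = (((np.arange(n_used)[:, None] >> np.arange(n_sub)) & 1) * 2 - 1)
    else:
        n_used = n_perm
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    max_null = np.empty(n_used)
    for i in range(n_used):
        max_null[i] = np.max(np.abs(tstats(signs[i][:, None] * Dok)))
    p_cor = np.full(n_roi, np.nan)
    if exhaustive:
        for r in np.flatnonzero(ok):
            p_cor[r] = np.mean(max_null >= np.abs(t_obs[r]) - 1e-12)
    else:
        for r in np.flatnonzero(ok):
            k = np.sum(max_null >= np.abs(t_obs[r]) - 1e-12)
            p_cor[r] = (k + 1) / (n_used + 1)
    p_cor = np.where(ok, np.maximum(p_cor, p_unc), np.nan)

    table = pd.DataFrame({
        "roi": roi_names,
        "mean_a": A.mean(axis=0), "sd_a": A.std(axis=0, ddof=1),
        "mean_b": B.mean(axis=0), "sd_b": B.std(axis=0, ddof=1),
        "t": t_obs, "p_uncorrected": p_unc, "p_corrected": p_cor,
    })
    return ROIFamilyResult(table=table, n_perm=n_used,
                           exhaustive=exhaustive, excluded=excluded)
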