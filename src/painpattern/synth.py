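"""Synthetic BOLD datasets with the statistical structure the decoding
pipeline assumes.

Two experimental designs are emulated:

* ``event_related_4mod`` — four sensory modalities (pain, touch, audition,
  vision) delivered pseudo-randomly within each run (default: 4 runs of
  32 stimuli, 8 per modality, inter-stimulus interval 10-19 s, TR 3 s, with
  fewer than 3 consecutive stimuli of the same modality), each stimulus
  followed by a saliency rating on a 0-10 scale.
* ``blocked_2mod`` — pain and touch delivered in blocks (default: per
  session 3 pain blocks and 3 touch blocks of 4 trials each, two intensity
  levels targeted at ratings 3 and 6, TR 0.8 s), each trial rated for
  perceived intensity.

Evoked responses are impulses at stimulus onsets scaled per voxel by a
modality-specific spatial pattern (with per-subject amplitude jitter) plus a
shared intensity-graded pattern scaled by the trial rating, convolved with
the canonical double-gamma HRF, superimposed on baseline plus AR(1)+white
noise. The ground-truth patterns and ROI masks are returned alongside the
data so recovery tests can score sensitivity maps against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .hrf import double_gamma_hrf
from .images import VolumeSeries
from .masks import Mask, split_mask_lr

__all__ = [
    "MODALITIES_EVENT", "MODALITIES_BLOCKED",
    "RatingModel", "MotionModel", "SyntheticConfig",
    "GroundTruth", "RunData", "SubjectRecord",
    "generate_events", "generate_ratings", "generate_motion",
    "make_ground_truth", "generate_dataset", "generate_subject",
]

MODALITIES_EVENT = ("pain", "touch", "audition", "vision")
MODALITIES_BLOCKED = ("pain", "touch")

EVENT_COLUMNS = ["onset_s", "modality", "level", "rating", "run"]


@dataclass(frozen=True)
class RatingModel:
    """Rating distributions. ``means``/``sds`` are keyed by modality for the
    event-related design and by intensity level for the blocked design.
    Optional saliency/valence columns are generated correlated with the
    intensity rating at the given targets (Gaussian copula)."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    saliency_intensity_r: float | None = None
    valence_intensity_r: float | None = None


@dataclass(frozen=True)
class MotionModel:
    """Head-motion table model: random-walk drift (mm / radian per step) plus
    an optional stimulus-locked translation component; ``signal_coupling``
    leaks the motion trace into voxel time series through random loadings so
    the motion-regression stage has something real to remove."""

    drift_sd: float = 0.01
    stimulus_locked_amp: float = 0.0
    signal_coupling: float = 0.0


def _default_rating_model_event() -> RatingModel:
    # saliency ratings roughly matched across modalities, mean ~5.5, SD ~2.2
    return RatingModel(
        means={m: 5.5 for m in MODALITIES_EVENT},
        sds={m: 2.2 for m in MODALITIES_EVENT},
    )


def _default_rating_model_blocked() -> RatingModel:
    return RatingModel(means={"low": 3.0, "high": 6.0},
                       sds={"low": 1.0, "high": 1.0})


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one synthetic cohort."""

    design: str = "event_related_4mod"
    n_subjects: int = 14
    grid_shape: tuple = (12, 12, 12)
    voxel_size: float = 3.0
    tr: float = 3.0
    n_runs: int = 4
    stimuli_per_run_per_modality: int = 8
    isi_range: tuple = (10.0, 19.0)
    # blocked design geometry
    blocks_per_modality: int = 3
    trials_per_block: int = 4
    trial_duration: float = 25.0
    stim_onset_in_trial: tuple = (2.0, 12.0)
    # signal model
    modality_pattern_amplitude: float | dict = 1.0
    shared_intensity_amplitude: float = 0.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    subject_pattern_jitter_sd: float = 0.1
    baseline: float = 100.0
    rating_model: RatingModel | None = None
    motion_model: MotionModel = field(default_factory=MotionModel)
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("event_related_4mod", "blocked_2mod"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.noise_sd < 0 or self.subject_pattern_jitter_sd < 0:
            raise ValueError("noise/jitter SDs must be non-negative")
        amps = self.amplitude_by_modality()
        if any(a < 0 for a in amps.values()):
            raise ValueError("pattern amplitudes must be non-negative")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.rating_model is None:
            rm = (_default_rating_model_event()
                  if self.design == "event_related_4mod"
                  else _default_rating_model_blocked())
            object.__setattr__(self, "rating_model", rm)

    @property
    def modalities(self) -> tuple:
        return (MODALITIES_EVENT if self.design == "event_related_4mod"
                else MODALITIES_BLOCKED)

    def amplitude_by_modality(self) -> dict:
        mods = (MODALITIES_EVENT if self.design == "event_related_4mod"
                else MODALITIES_BLOCKED)
        a = self.modality_pattern_amplitude
        if isinstance(a, dict):
            return {m: float(a.get(m, 0.0)) for m in mods}
        return {m: float(a) for m in mods}

    @classmethod
    def dataset1(cls, **kw) -> "SyntheticConfig":
        """Event-related four-modality cohort: 14 subjects, 4 runs of
        32 stimuli (8/modality), ISI 10-19 s, TR 3 s."""
        return cls(design="event_related_4mod", n_subjects=14, n_runs=4,
                   stimuli_per_run_per_modality=8, isi_range=(10.0, 19.0),
                   tr=3.0, **kw)

    @classmethod
    def dataset2(cls, **kw) -> "SyntheticConfig":
        """Blocked pain/touch cohort: 51 subjects, 2 sessions, per session
        3 pain + 3 touch blocks of 4 trials, levels rated near 3 and 6,
        TR 0.8 s."""
        return cls(design="blocked_2mod", n_subjects=51, n_runs=2,
                   tr=0.8, **kw)


@dataclass
class GroundTruth:
    """Injected spatial patterns and the ROI geometry of a cohort."""

    modality_patterns: dict          # modality -> 3D unit pattern (max 1)
    shared_pattern: np.ndarray       # 3D unit pattern for the rating-graded signal
    roi_mask: Mask
    subregion_masks: dict            # 10 named Masks partitioning the ROI
    brain_mask: Mask
    out_pattern: np.ndarray | None = None  # optional pattern outside the ROI

    def to_manifest(self) -> dict:
        return {
            "roi_voxels": self.roi_mask.voxel_count,
            "subregions": {k: v.voxel_count for k, v in self.subregion_masks.items()},
            "pattern_support": {m: int((p > 0).sum())
                                for m, p in self.modality_patterns.items()},
            "shared_pattern_support": int((self.shared_pattern > 0).sum()),
        }


@dataclass
class RunData:
    series: VolumeSeries
    events: pd.DataFrame
    motion: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad


@dataclass
class SubjectRecord:
    subject_id: str
    runs: list


# ---------------------------------------------------------------------------
# geometry / ground truth
# ---------------------------------------------------------------------------

def _centered_affine(grid_shape, voxel_size) -> np.ndarray:
    """Axis-aligned affine placing the grid center at world origin."""
    aff = np.diag([voxel_size] * 3 + [1.0]).astype(float)
    aff[:3, 3] = -voxel_size * (np.asarray(grid_shape) - 1) / 2.0
    return aff


def _grow_cluster(candidates: np.ndarray, center: np.ndarray, size: int) -> np.ndarray:
    """Indices (into candidates) of the ``size`` voxels nearest to center."""
    d = np.linalg.norm(candidates - center, axis=1)
    return np.argsort(d, kind="stable")[:size]


def make_ground_truth(config: SyntheticConfig, seed=None) -> GroundTruth:
    """Build the ROI, its 10 sub-regions, and disjoint per-modality pattern
    clusters plus a shared intensity-graded cluster inside the ROI.

    The ROI is a central ellipsoid covering roughly half the grid; the 10
    sub-regions partition it left/right x five superior-inferior slabs,
    mimicking a bilateral set of regions. Pattern clusters are compact
    groups of ROI voxels (about 8% of the ROI each), pairwise disjoint so
    sensitivity-map recovery can be scored unambiguously.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5]))
    shape = np.asarray(config.grid_shape)
    if np.any(shape < 8):
        raise ValueError("grid_shape must be at least 8 voxels per axis")
    affine = _centered_affine(config.grid_shape, config.voxel_size)

    i, j, k = np.indices(config.grid_shape)
    c = (shape - 1) / 2.0
    r = shape / 2.0
    ell = (((i - c[0]) / r[0]) ** 2 + ((j - c[1]) / r[1]) ** 2
           + ((k - c[2]) / r[2]) ** 2)
    brain = Mask(ell <= 1.0, affine)
    roi = Mask(ell <= 0.55, affine)

    # sub-regions: left/right split x 5 slabs along z
    lr = split_mask_lr(roi)
    region_names = ["S1", "S2", "insula", "cingulate", "thalamus"]
    subregions = {}
    for side in ("left", "right"):
        m = lr[side]
        kk = np.nonzero(m.data)[2]
        edges = np.quantile(kk, np.linspace(0, 1, 6)) if kk.size else np.zeros(6)
        for idx, name in enumerate(region_names):
            lo, hi = edges[idx], edges[idx + 1]
            sel = (k >= lo) & ((k < hi) if idx < 4 else (k <= hi))
            subregions[f"{side}_{name}"] = Mask(m.data & sel, affine)

    # disjoint clusters for each modality + the shared pattern
    roi_ijk = np.column_stack(np.nonzero(roi.data))
    n_roi = len(roi_ijk)
    cluster_size = max(4, int(round(0.08 * n_roi)))
    available = np.ones(n_roi, dtype=bool)
    patterns = {}
    names = list(config.modalities) + ["__shared__"]
    for name in names:
        avail_idx = np.flatnonzero(available)
        if len(avail_idx) < cluster_size:
            raise ValueError("ROI too small for disjoint pattern clusters")
        center = roi_ijk[rng.choice(avail_idx)]
        picked = avail_idx[_grow_cluster(roi_ijk[avail_idx], center, cluster_size)]
        available[picked] = False
        vol = np.zeros(config.grid_shape)
        sel = roi_ijk[picked]
        vol[sel[:, 0], sel[:, 1], sel[:, 2]] = 1.0
        patterns[name] = vol

    shared = patterns.pop("__shared__")

    # optional out-of-ROI cluster (in brain, outside ROI); unit amplitude,
    # used only when a caller injects signal through it explicitly
    out_data = brain.data & ~roi.data
    out_ijk = np.column_stack(np.nonzero(out_data))
    out_pattern = None
    if len(out_ijk) >= cluster_size:
        center = out_ijk[rng.choice(len(out_ijk))]
        picked = _grow_cluster(out_ijk, center, cluster_size)
        out_pattern = np.zeros(config.grid_shape)
        sel = out_ijk[picked]
        out_pattern[sel[:, 0], sel[:, 1], sel[:, 2]] = 1.0

    return GroundTruth(modality_patterns=patterns, shared_pattern=shared,
                       roi_mask=roi, subregion_masks=subregions,
                       brain_mask=brain, out_pattern=out_pattern)


# ---------------------------------------------------------------------------
# events, ratings, motion
# ---------------------------------------------------------------------------

def _max_run_length(seq) -> int:
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best if seq else 0


def _event_related_sequence(rng, n_per_mod: int) -> list:
    """Pseudo-random modality order with < 3 consecutive repeats."""
    labels = [m for m in MODALITIES_EVENT for _ in range(n_per_mod)]
    for _ in range(1000):
        rng.shuffle(labels)
        if _max_run_length(labels) < 3:
            return list(labels)
    # repair fallback: swap offending entries forward
    for idx in range(2, len(labels)):
        while labels[idx] == labels[idx - 1] == labels[idx - 2]:
            swap = rng.integers(0, len(labels))
            labels[idx], labels[swap] = labels[swap], labels[idx]
    return list(labels)


def generate_events(config: SyntheticConfig, run: int, rng) -> pd.DataFrame:
    """Stimulus table for one run/session (without ratings)."""
    if config.design == "event_related_4mod":
        seq = _event_related_sequence(rng, config.stimuli_per_run_per_modality)
        isis = rng.uniform(*config.isi_range, size=len(seq))
        onsets = np.cumsum(isis)
        return pd.DataFrame({
            "onset_s": onsets, "modality": seq, "level": None,
            "rating": np.nan, "run": run,
        })
    # blocked_2mod: shuffled block order, fixed trial grid
    blocks = (["pain"] * config.blocks_per_modality
              + ["touch"] * config.blocks_per_modality)
    rng.shuffle(blocks)
    rows = []
    # per modality, half the trials low and half high, shuffled
    n_trials_mod = config.blocks_per_modality * config.trials_per_block
    levels = {}
    for m in MODALITIES_BLOCKED:
        lv = ["low"] * (n_trials_mod // 2) + ["high"] * (n_trials_mod - n_trials_mod // 2)
        rng.shuffle(lv)
        levels[m] = lv
    counters = {m: 0 for m in MODALITIES_BLOCKED}
    t0 = 0.0
    for b, mod in enumerate(blocks):
        for tidx in range(config.trials_per_block):
            trial_start = t0 + tidx * config.trial_duration
            onset = trial_start + rng.uniform(*config.stim_onset_in_trial)
            rows.append({"onset_s": onset, "modality": mod,
                         "level": levels[mod][counters[mod]],
                         "rating": np.nan, "run": run})
            counters[mod] += 1
        t0 += config.trials_per_block * config.trial_duration
    return pd.DataFrame(rows).sort_values("onset_s").reset_index(drop=True)


def _correlated_column(rng, z_intensity: np.ndarray, target_r: float,
                       mean: float, sd: float) -> np.ndarray:
    if not (-1.0 < target_r < 1.0):
        raise ValueError("correlation target must lie in (-1, 1)")
    noise = rng.standard_normal(len(z_intensity))
    z = target_r * z_intensity + np.sqrt(1 - target_r ** 2) * noise
    return np.clip(mean + sd * z, 0.0, 10.0)


def generate_ratings(config: SyntheticConfig, events: pd.DataFrame,
                     rng=None) -> pd.DataFrame:
    """Fill the rating column (clipped to [0, 10]); optionally add saliency
    and valence columns correlated with intensity at the configured targets."""
    events = events.copy()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(events) == 0:
        return events
    rm = config.rating_model
    if config.design == "event_related_4mod":
        keys = events["modality"]
    else:
        keys = events["level"]
    means = keys.map(rm.means).to_numpy(dtype=float)
    sds = keys.map(rm.sds).to_numpy(dtype=float)
    z = rng.standard_normal(len(events))
    rating = np.clip(means + sds * z, 0.0, 10.0)
    events["rating"] = rating
    if rm.saliency_intensity_r is not None or rm.valence_intensity_r is not None:
        # standardize the realized ratings so level structure counts toward
        # the correlation target
        sd_tot = rating.std()
        z_tot = ((rating - rating.mean()) / sd_tot if sd_tot > 0
                 else np.zeros_like(rating))
        if rm.saliency_intensity_r is not None:
            events["saliency"] = _correlated_column(
                rng, z_tot, rm.saliency_intensity_r, rating.mean(), max(sd_tot, 1e-12))
        if rm.valence_intensity_r is not None:
            events["valence"] = _correlated_column(
                rng, z_tot, rm.valence_intensity_r, rating.mean(), max(sd_tot, 1e-12))
    return events


def generate_motion(config: SyntheticConfig, events: pd.DataFrame,
                    n_volumes: int, rng) -> np.ndarray:
    """6-column motion table: random-walk drift (rotations scaled to stay
    small in radians) plus an optional HRF-shaped stimulus-locked bump on the
    first translation axis."""
    mm = config.motion_model
    steps = rng.normal(0.0, mm.drift_sd, size=(n_volumes, 6))
    steps[:, 3:] /= 50.0  # keep rotations on a comparable displacement scale
    motion = np.cumsum(steps, axis=0)
    if mm.stimulus_locked_amp > 0 and len(events):
        t = np.arange(n_volumes) * config.tr
        bump = np.zeros(n_volumes)
        for onset in events["onset_s"].to_numpy():
            bump += double_gamma_hrf(t - onset)
        motion[:, 0] += mm.stimulus_locked_amp * bump
    return motion


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _ar1_plus_white(rng, shape, sd, phi):
    """AR(1) and white components each carrying half the total variance."""
    if sd == 0:
        return np.zeros(shape)
    sd_c = sd / np.sqrt(2.0)
    w = rng.normal(0.0, sd_c * np.sqrt(1 - phi ** 2), size=shape)
    ar = lfilter([1.0], [1.0, -phi], w, axis=-1)
    return ar + rng.normal(0.0, sd_c, size=shape)


def _subject_seed(config: SyntheticConfig, s: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(config.seed), 0xD5]).spawn(
        config.n_subjects)[s]


def generate_subject(config: SyntheticConfig, truth: GroundTruth,
                     s: int) -> SubjectRecord:
    """Generate one subject's runs; identical to the corresponding entry of
    :func:`generate_dataset` output, allowing large cohorts to be processed
    one subject at a time."""
    affine = truth.roi_mask.affine
    amps = config.amplitude_by_modality()
    n_vox = int(np.prod(config.grid_shape))
    unit = {m: truth.modality_patterns[m].reshape(n_vox)
            for m in config.modalities}
    shared = truth.shared_pattern.reshape(n_vox)

    rng = np.random.default_rng(_subject_seed(config, s))
    jitter = {m: rng.normal(0.0, config.subject_pattern_jitter_sd)
              for m in config.modalities}
    runs = []
    for run in range(config.n_runs):
        events = generate_events(config, run, rng)
        events = generate_ratings(config, events, rng)
        duration = float(events["onset_s"].iloc[-1]) + 25.0 \
            if config.design == "event_related_4mod" \
            else (2 * config.blocks_per_modality
                  * config.trials_per_block * config.trial_duration)
        n_volumes = int(np.ceil(duration / config.tr))
        t = np.arange(n_volumes) * config.tr

        # event design: H[e, t] = hrf(t - onset_e)
        onsets = events["onset_s"].to_numpy()
        H = double_gamma_hrf(t[None, :] - onsets[:, None])
        # per-voxel amplitude of each event
        A = np.zeros((n_vox, len(events)))
        for e, (mod, rating) in enumerate(
                zip(events["modality"], events["rating"])):
            # additive amplitude jitter; not rectified at 0, so a zero
            # base amplitude stays signal-free in expectation
            amp = amps[mod] + jitter[mod]
            A[:, e] = unit[mod] * amp
            if config.shared_intensity_amplitude and np.isfinite(rating):
                A[:, e] += shared * config.shared_intensity_amplitude * rating
        signal = A @ H

        noise = _ar1_plus_white(rng, (n_vox, n_volumes),
                                config.noise_sd, config.ar1_coef)
        motion = generate_motion(config, events, n_volumes, rng)
        data = config.baseline + signal + noise
        if config.motion_model.signal_coupling:
            loadings = rng.normal(0.0, 1.0, size=(n_vox, 6))
            data += config.motion_model.signal_coupling * (loadings @ motion.T)
        series = VolumeSeries(
            data.reshape(*config.grid_shape, n_volumes), affine, config.tr)
        runs.append(RunData(series=series, events=events, motion=motion))
    return SubjectRecord(subject_id=f"sub-{s:02d}", runs=runs)


def generate_dataset(config: SyntheticConfig,
                     truth: GroundTruth | None = None) -> dict:
    """Generate a full cohort.

    Returns ``{"subjects": [SubjectRecord, ...], "truth": GroundTruth,
    "config": config}``. Identical configs (including seed) give bit-identical
    output. Pass ``truth`` to reuse the spatial patterns of another cohort on
    the same grid (for cross-dataset experiments).
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if truth is None:
        truth = make_ground_truth(config)
    subjects = [generate_subject(config, truth, s)
                for s in range(config.n_subjects)]
    return {"subjects": subjects, "truth": truth, "config": config}
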