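"""Study-condition cohort definitions and one-pass accessors shared by the
numbered analysis drivers.

Cohort 1 emulates the event-related four-modality experiment (14 subjects,
4 runs x 32 stimuli, TR 3 s, saliency ratings); cohort 2 the blocked
pain/touch experiment (51 subjects, 2 sessions, 2 intensity levels rated
near 3 and 6, TR 0.8 s). The blocked cohort is processed one subject at a
time so full 4D volumes never accumulate in memory.
"""

from __future__ import annotations

import numpy as np

from painpattern import (RatingModel, SyntheticConfig, make_ground_truth,
                         match_trials_greedy, roi_normalize)
from painpattern.pipeline import (average_samples, iter_subject_records,
                                  preprocess_run)
from painpattern.preprocess import summarize_motion
from painpattern.univariate import roi_mean_signal

GRID = (14, 13, 13)
RESULTS_DIR = "results"

# pattern amplitude 1.0 per modality against unit noise: with 32 trials
# averaged per modality this supports near-ceiling within-cohort decoding,
# the regime the decoding experiments operate in
COMMON_SIGNAL = dict(
    grid_shape=GRID, modality_pattern_amplitude=1.0,
    shared_intensity_amplitude=0.08, noise_sd=1.0,
    subject_pattern_jitter_sd=0.15,
)


def dataset1_config(seed: int = 101) -> SyntheticConfig:
    return SyntheticConfig.dataset1(**COMMON_SIGNAL, seed=seed)


def shared_truth():
    """One ground truth for both cohorts: the two experiments record the
    same underlying 'brain', so cross-cohort transfer is meaningful."""
    return make_ground_truth(dataset1_config())


def dataset2_config(seed: int = 202) -> SyntheticConfig:
    return SyntheticConfig.dataset2(
        **COMMON_SIGNAL,
        rating_model=RatingModel(means={"low": 3.0, "high": 6.0},
                                 sds={"low": 1.0, "high": 1.0},
                                 saliency_intensity_r=0.86,
                                 valence_intensity_r=-0.49),
        seed=seed)


def collect_cohort(config, truth=None, match_tol=None):
    """Stream a cohort through preprocessing once and keep only the small
    derived objects.

    Returns a dict with, per subject: trial-level pattern samples (ROI
    voxels), per-modality averaged samples (raw and ROI-normalized), mean
    framewise displacement per modality, and — when ``match_tol`` is given —
    the per-subject greedy pain/touch trial pairing and the averaged samples
    restricted to matched trials.
    """
    out = {"subjects": [], "trial_samples": [], "modality_samples": [],
           "matched_samples": [], "motion_fd": [], "pairings": {}}
    for record, truth in iter_subject_records(config, truth):
        sid = record.subject_id
        out["subjects"].append(sid)
        trials = []
        per_run = []
        for run in record.runs:
            run_samples = preprocess_run(run, truth.roi_mask)
            for s in run_samples:
                s.meta["subject"] = sid
            trials.extend(run_samples)
            per_run.extend(average_samples(run_samples, by=("modality", "run")))
            for mod in config.modalities:
                if (run.events["modality"] == mod).any():
                    out["motion_fd"].append({
                        "subject": sid, "modality": mod, "run": run.events["run"].iloc[0],
                        "fd_mm": summarize_motion(run.motion, run.events, mod,
                                                  config.tr)})
        averaged = average_samples(per_run, by=("modality",))
        for s in averaged:
            s.meta["subject"] = sid
        out["trial_samples"].extend(trials)
        out["modality_samples"].extend(averaged)

        if match_tol is not None:
            pain = [s for s in trials if s.meta["modality"] == "pain"]
            touch = [s for s in trials if s.meta["modality"] == "touch"]
            pairing = match_trials_greedy([s.meta["rating"] for s in pain],
                                          [s.meta["rating"] for s in touch],
                                          tol=match_tol)
            out["pairings"][sid] = pairing
            kept_pain = [pain[i] for i, _, _ in pairing.pairs]
            kept_touch = [touch[j] for _, j, _ in pairing.pairs]
            for group in (kept_pain, kept_touch):
                if not group:
                    continue
                (avg,) = average_samples(group, by=("modality",))
                avg.meta["subject"] = sid
                avg.meta["rating"] = float(np.mean(
                    [t.meta["rating"] for t in group]))
                out["matched_samples"].append(avg)
    out["truth"] = truth
    out["config"] = config
    return out


def subregion_means(samples, truth) -> dict:
    """Per-sample mean signal in each of the 10 sub-region masks."""
    table = {}
    for s in samples:
        row = {name: roi_mean_signal(s, truth.roi_mask, m)
               for name, m in truth.subregion_masks.items()}
        table[(s.meta["subject"], s.meta["modality"])] = row
    return table


def normalized(samples):
    return [roi_normalize(s) for s in samples]
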