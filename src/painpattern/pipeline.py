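"""End-to-end workflows tying the generator, preprocessing and decoding
together; the analysis drivers, tests and acceptance checks all run through
these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .masks import Mask
from .mvpa import SampleSet, loso_classify, permutation_null
from .preprocess import (PatternSample, average_samples, detrend_zscore,
                         extract_peak_samples, regress_out_motion,
                         roi_normalize)
from .synth import (GroundTruth, SubjectRecord, SyntheticConfig,
                    generate_subject, make_ground_truth)

__all__ = [
    "default_peak_offset", "preprocess_run", "subject_modality_samples",
    "trial_samples", "build_modality_sampleset", "decode_modalities",
    "subject_rating_differences", "iter_subject_records",
]


def iter_subject_records(config: SyntheticConfig,
                         truth: GroundTruth | None = None):
    """Yield ``(SubjectRecord, GroundTruth)`` one subject at a time, so large
    cohorts never sit in memory whole; output matches generate_dataset."""
    if truth is None:
        truth = make_ground_truth(config)
    for s in range(config.n_subjects):
        yield generate_subject(config, truth, s), truth


def default_peak_offset(tr: float) -> int:
    """Volumes after onset whose acquisition lands near the ~6 s BOLD peak
    (2 for TR 3 s, 8 for TR 0.8 s)."""
    return max(1, int(round(6.0 / tr)))


def preprocess_run(run, mask: Mask, peak_offset: int | None = None,
                   order: tuple = ("motion", "detrend")) -> list:
    """Motion regression and detrend/z-score (configurable order), then
    peak-volume extraction restricted to the mask. Returns one PatternSample
    per event, carrying the event's metadata."""
    series = run.series
    for step in order:
        if step == "motion":
            series = regress_out_motion(series, run.motion)
        elif step == "detrend":
            series = detrend_zscore(series)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    if peak_offset is None:
        peak_offset = default_peak_offset(series.tr)
    return extract_peak_samples(series, run.events, mask, peak_offset)


def trial_samples(dataset: dict, mask: Mask, peak_offset: int | None = None,
                  order: tuple = ("motion", "detrend")) -> list:
    """Trial-level samples for a whole cohort, tagged with subject ids."""
    out = []
    for record in dataset["subjects"]:
        for run in record.runs:
            for s in preprocess_run(run, mask, peak_offset, order):
                s.meta["subject"] = record.subject_id
                out.append(s)
    return out


def subject_modality_samples(record: SubjectRecord, mask: Mask,
                             peak_offset: int | None = None,
                             order: tuple = ("motion", "detrend")) -> list:
    """One averaged sample per modality for one subject: trials are averaged
    within each modality and run, then across runs."""
    per_run = []
    for run in record.runs:
        samples = preprocess_run(run, mask, peak_offset, order)
        per_run.extend(average_samples(samples, by=("modality", "run")))
    averaged = average_samples(per_run, by=("modality",))
    for s in averaged:
        s.meta["subject"] = record.subject_id
    return averaged


def build_modality_sampleset(dataset: dict, mask: Mask,
                             positive: str = "pain", negative: str = "touch",
                             normalize: bool = True,
                             subjects: list | None = None,
                             peak_offset: int | None = None,
                             order: tuple = ("motion", "detrend"),
                             dataset_id: str = "") -> SampleSet:
    """Per-subject per-modality averaged samples for a two-way
    classification, optionally ROI-normalized."""
    samples = []
    for record in dataset["subjects"]:
        if subjects is not None and record.subject_id not in subjects:
            continue
        for s in subject_modality_samples(record, mask, peak_offset, order):
            if s.meta["modality"] in (positive, negative):
                samples.append(roi_normalize(s) if normalize else s)
    return SampleSet.from_samples(samples, class_key="modality",
                                  positive_class=positive,
                                  dataset_id=dataset_id)


def decode_modalities(dataset: dict, mask: Mask | None = None,
                      positive: str = "pain", negative: str = "touch",
                      normalize: bool = True, n_perm: int = 0, seed: int = 0,
                      subjects: list | None = None, C: float = 1.0):
    """LOSO decoding of one modality pair; with ``n_perm`` > 0 the
    permutation null and p-value are attached."""
    if mask is None:
        mask = dataset["truth"].roi_mask
    sset = build_modality_sampleset(dataset, mask, positive, negative,
                                    normalize=normalize, subjects=subjects)
    if n_perm:
        return permutation_null(sset, n_perm=n_perm, seed=seed, C=C), sset
    return loso_classify(sset, C=C), sset


def subject_rating_differences(dataset: dict, a: str = "pain",
                               b: str = "touch") -> dict:
    """Per-subject mean rating difference (modality a minus modality b),
    the input to subject counterbalancing."""
    diffs = {}
    for record in dataset["subjects"]:
        events = pd.concat([run.events for run in record.runs])
        ma = events.loc[events["modality"] == a, "rating"].mean()
        mb = events.loc[events["modality"] == b, "rating"].mean()
        diffs[record.subject_id] = float(ma - mb)
    return diffs
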