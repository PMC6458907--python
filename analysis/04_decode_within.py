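#!/usr/bin/env python
"""Within-cohort between-subject decoding.

Cohort 1: LOSO "pain vs touch/audition/vision" on ROI-normalized peak
samples in the saliency-counterbalanced subgroups, with permutation nulls,
sensitivity maps, the consistent-sign (pain-preferring) map across the
three classifications, per-sub-region classifications, a beta-map variant
of "pain vs touch", and the high/low-saliency median-split classification.

Cohort 2: LOSO "pain vs touch" on intensity-matched trials, plus the
high/low-intensity classification built by pooled median split.

JSON results go to results/; sensitivity maps (NIfTI) and null-distribution
dumps to scratch/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohorts import (collect_cohort, dataset1_config, dataset2_config,
                     normalized, shared_truth)
from painpattern import (SampleSet, balance_classes_by_modality,
                         consistent_sign_map, glm_betas,
                         median_split_classes, permutation_null,
                         pooled_median_split_average, roi_normalize,
                         select_counterbalanced_subjects, sensitivity_map)
from painpattern.preprocess import PatternSample
from painpattern.pipeline import iter_subject_records

RESULTS = Path("results")
SCRATCH = Path("scratch")
N_PERM = 5000
N_PERM_SUBREGION = 1000


def to_sampleset(samples, positive, negative, subjects=None, class_key="modality"):
    keep = [s for s in samples
            if str(s.meta[class_key]) in (positive, negative)
            and (subjects is None or s.meta["subject"] in subjects)]
    return SampleSet.from_samples(keep, class_key=class_key,
                                  positive_class=positive,
                                  keep=("modality", "rating", class_key))


def run_classification(name, sset, mask=None, n_perm=N_PERM, seed=11,
                       save_map=True):
    res = permutation_null(sset, n_perm=n_perm, seed=seed)
    print(f"{name}: accuracy {res.accuracy:.2f}, p {res.p_report} "
          f"({n_perm} permutations)")
    entry = res.to_dict()
    if save_map and mask is not None:
        smap = sensitivity_map(res, mask)
        smap.to_nifti().to_filename(SCRATCH / f"map_{name}.nii.gz")
        np.savetxt(SCRATCH / f"null_{name}.tsv", res.null_accuracies)
        entry["map_file"] = f"scratch/map_{name}.nii.gz"
    return res, entry


def subregion_sampleset(sset, parent_mask, region_mask):
    parent_idx = np.column_stack(parent_mask.indices())
    flags = region_mask.data[parent_idx[:, 0], parent_idx[:, 1],
                             parent_idx[:, 2]]
    return SampleSet(sset.X[:, flags], sset.y, sset.subjects,
                     sset.positive_class, sset.meta, sset.normalized,
                     sset.dataset_id)


def dataset1(report):
    cfg = dataset1_config()
    c1 = collect_cohort(cfg)
    truth = c1["truth"]
    ratings = pd.DataFrame(
        [{"subject": s.meta["subject"], "modality": s.meta["modality"],
          "rating": s.meta["rating"]} for s in c1["trial_samples"]])
    mean_rating = ratings.groupby(["subject", "modality"])["rating"].mean()
    norm_samples = normalized(c1["modality_samples"])

    maps = []
    for other in ("touch", "audition", "vision"):
        diffs = {sub: float(mean_rating[sub]["pain"] - mean_rating[sub][other])
                 for sub in c1["subjects"]}
        subgroup = select_counterbalanced_subjects(diffs)
        sset = to_sampleset(norm_samples, "pain", other, subjects=subgroup)
        res, entry = run_classification(f"d1_pain_vs_{other}", sset,
                                        truth.roi_mask)
        report[f"d1_pain_vs_{other}"] = entry
        maps.append(sensitivity_map(res, truth.roi_mask))

        if other == "touch":
            # per-sub-region classifications
            sub_acc = {}
            for rname, rmask in sorted(truth.subregion_masks.items()):
                rset = subregion_sampleset(sset, truth.roi_mask, rmask)
                rres = permutation_null(rset, n_perm=N_PERM_SUBREGION,
                                        seed=13)
                sub_acc[rname] = {"accuracy": rres.accuracy,
                                  "p": rres.p_value,
                                  "p_report": rres.p_report}
            report["d1_subregions_pain_vs_touch"] = sub_acc
            best = max(sub_acc, key=lambda k: sub_acc[k]["accuracy"])
            print(f"  sub-regions: accuracies "
                  f"{min(v['accuracy'] for v in sub_acc.values()):.2f}-"
                  f"{sub_acc[best]['accuracy']:.2f} (best {best})")

    consistent = consistent_sign_map(maps)
    consistent.to_nifti().to_filename(SCRATCH / "map_d1_pain_preferring.nii.gz")
    n_pos = int((consistent.values > 0).sum())
    print(f"  consistent-sign map: {n_pos} pain-preferring voxels "
          f"of {truth.roi_mask.voxel_count}")
    report["d1_pain_preferring_voxels"] = n_pos

    # beta-map variant of pain vs touch (same subgroup as the peak variant)
    diffs = {sub: float(mean_rating[sub]["pain"] - mean_rating[sub]["touch"])
             for sub in c1["subjects"]}
    subgroup = select_counterbalanced_subjects(diffs)
    beta_samples = []
    for rec, _ in iter_subject_records(cfg, truth):
        if rec.subject_id not in subgroup:
            continue
        per_run = {m: [] for m in ("pain", "touch")}
        for run in rec.runs:
            betas = glm_betas(run.series, run.events, run.motion)
            for m in per_run:
                per_run[m].append(betas[m][truth.roi_mask.indices()])
        for m, vals in per_run.items():
            beta_samples.append(roi_normalize(PatternSample(
                np.mean(vals, axis=0),
                meta={"subject": rec.subject_id, "modality": m})))
    bset = SampleSet.from_samples(beta_samples, class_key="modality",
                                  positive_class="pain")
    _, entry = run_classification("d1_beta_pain_vs_touch", bset,
                                  truth.roi_mask)
    report["d1_beta_pain_vs_touch"] = entry

    # high vs low saliency: median split of the 56 per-modality samples
    rated = []
    for s in norm_samples:
        s2 = PatternSample(s.values, meta=dict(s.meta), normalized=True)
        s2.meta["rating"] = float(
            mean_rating[s.meta["subject"]][s.meta["modality"]])
        rated.append(s2)
    split = median_split_classes(rated)
    balanced = balance_classes_by_modality(split)
    print(f"  high/low saliency: {balanced.n_samples} samples after "
          f"per-modality balancing")
    _, entry = run_classification("d1_high_vs_low", balanced, truth.roi_mask)
    report["d1_high_vs_low"] = entry


def dataset2(report):
    c2 = collect_cohort(dataset2_config(), truth=shared_truth(), match_tol=0.5)
    truth = c2["truth"]
    matched = normalized(c2["matched_samples"])
    sset = to_sampleset(matched, "pain", "touch")
    _, entry = run_classification("d2_pain_vs_touch", sset, truth.roi_mask)
    report["d2_pain_vs_touch"] = entry

    # high vs low intensity: pooled median split of all trials, discard
    # one-class participants, average per modality x participant x class
    trial_norm = normalized(c2["trial_samples"])
    hl = pooled_median_split_average(trial_norm)
    print(f"  high/low intensity: {hl.n_samples} samples "
          f"({(hl.y == 'high').sum()} per class)")
    _, entry = run_classification("d2_high_vs_low", hl, truth.roi_mask)
    report["d2_high_vs_low"] = entry


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    report = {}
    print("== cohort 1 ==")
    dataset1(report)
    print("== cohort 2 ==")
    dataset2(report)
    out = RESULTS / "decoding_within.json"
    out.write_text(json.dumps(report, indent=2, default=str) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
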