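#!/usr/bin/env python
"""Cross-cohort generalization: train the linear SVM on one cohort's
ROI-normalized samples and test on the other, both for "pain vs touch" and
for "high vs low intensity/saliency"; permutation nulls retrain on
label-permuted training data. The two cohorts share one ground truth, so
transferable structure exists by construction.
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
                         consistent_sign_map, cross_dataset_classify,
                         median_split_classes, pooled_median_split_average,
                         select_counterbalanced_subjects, sensitivity_map)
from painpattern.preprocess import PatternSample

RESULTS = Path("results")
SCRATCH = Path("scratch")
N_PERM = 5000


def pain_touch_set(samples, subjects=None, dataset_id=""):
    keep = [s for s in samples if s.meta["modality"] in ("pain", "touch")
            and (subjects is None or s.meta["subject"] in subjects)]
    return SampleSet.from_samples(keep, class_key="modality",
                                  positive_class="pain",
                                  dataset_id=dataset_id)


def crossed(name, train, test, mask, report, seed=17):
    res = cross_dataset_classify(train, test, n_perm=N_PERM, seed=seed)
    print(f"{name}: accuracy {res.accuracy:.2f}, p {res.p_report}")
    report[name] = res.to_dict()
    smap = sensitivity_map(res, mask)
    smap.to_nifti().to_filename(SCRATCH / f"map_{name}.nii.gz")
    return smap


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    truth = shared_truth()
    mask = truth.roi_mask
    report = {}

    c1 = collect_cohort(dataset1_config(), truth=truth)
    c2 = collect_cohort(dataset2_config(), truth=truth, match_tol=0.5)

    # pain vs touch, saliency/intensity-matched samples in both cohorts
    ratings = pd.DataFrame(
        [{"subject": s.meta["subject"], "modality": s.meta["modality"],
          "rating": s.meta["rating"]} for s in c1["trial_samples"]])
    mean_rating = ratings.groupby(["subject", "modality"])["rating"].mean()
    diffs = {sub: float(mean_rating[sub]["pain"] - mean_rating[sub]["touch"])
             for sub in c1["subjects"]}
    subgroup = select_counterbalanced_subjects(diffs)
    set1 = pain_touch_set(normalized(c1["modality_samples"]),
                          subjects=subgroup, dataset_id="cohort1")
    set2 = pain_touch_set(normalized(c2["matched_samples"]),
                          dataset_id="cohort2")
    m12 = crossed("train_c1_test_c2_pain_vs_touch", set1, set2, mask, report)
    m21 = crossed("train_c2_test_c1_pain_vs_touch", set2, set1, mask, report)
    overlap = consistent_sign_map([m12, m21])
    overlap.to_nifti().to_filename(SCRATCH / "map_cross_consistent.nii.gz")
    n_cons = int((overlap.values != 0).sum())
    print(f"consistent-sign voxels across both directions: {n_cons}")
    report["cross_consistent_sign_voxels"] = n_cons

    # high vs low intensity/saliency
    rated = []
    for s in normalized(c1["modality_samples"]):
        s2 = PatternSample(s.values, meta=dict(s.meta), normalized=True)
        s2.meta["rating"] = float(
            mean_rating[s.meta["subject"]][s.meta["modality"]])
        rated.append(s2)
    hl1 = balance_classes_by_modality(median_split_classes(rated))
    hl2 = pooled_median_split_average(normalized(c2["trial_samples"]))
    crossed("train_c1_test_c2_high_vs_low", hl1, hl2, mask, report)
    crossed("train_c2_test_c1_high_vs_low", hl2, hl1, mask, report)

    out = RESULTS / "decoding_across.json"
    out.write_text(json.dumps(report, indent=2, default=str) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
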