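"""End-to-end orchestration over simulated or loaded cohorts.

The canonical flow for each sample:

raw calls -> informative-SNP collection (pre-filtering, needs common SNPs)
          -> leave-one-out PoN subtraction -> prefilter -> truth labels
          -> feature rows

Cohort-level helpers stack the per-sample results into one feature matrix
and summarize per-sample TMB / MVTSM / TPR for the evaluation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluate import SampleSummary
from .features import FeatureMatrix, assemble_feature_matrix, collect_informative_snps
from .labels import attach_labels
from .pon import apply_pon, build_loo_pon, normalize_key
from .prefilter import FilterConfig, apply_prefilter, count_to_classify
from .simulate import SimulatedSample, mvtsm
from .tmb import compute_tmb

__all__ = ["CohortFeatures", "featurize_cohort", "summarize_cohort"]


@dataclass
class CohortFeatures:
    matrix: FeatureMatrix
    kept_by_sample: dict[str, list]
    samples: list[SimulatedSample]


def featurize_cohort(
    samples: Sequence[SimulatedSample],
    filter_config: FilterConfig | None = None,
    min_recurrence: int = 2,
    use_pon: bool = True,
) -> CohortFeatures:
    """Run PoN + prefilter + labeling + feature assembly over a cohort."""
    normal_sets = {
        s.patient_id: {normalize_key(*k) for k in s.normal_keys} for s in samples
    }
    kept_by_sample: dict[str, list] = {}
    snps_by_sample: dict[str, list] = {}
    for s in samples:
        snps_by_sample[s.patient_id] = collect_informative_snps(s.variants, s.segments)
        variants = s.variants
        if use_pon and len(samples) >= 3:
            panel = build_loo_pon(normal_sets, s.patient_id, min_recurrence=min_recurrence)
            variants, _removed = apply_pon(variants, panel)
        kept, _log = apply_prefilter(variants, filter_config)
        kept_by_sample[s.patient_id] = attach_labels(kept, s.somatic_keys)

    counts = count_to_classify(
        [v for kept in kept_by_sample.values() for v in kept]
    )
    # features are computed against each sample's own segments; the stacked
    # matrix keeps per-sample blocks in cohort order
    frames, label_frames = [], []
    columns = None
    for s in samples:
        sub = assemble_feature_matrix(
            kept_by_sample[s.patient_id], snps_by_sample[s.patient_id], s.segments, counts
        )
        columns = sub.columns
        frames.append(sub.data)
        label_frames.append(sub.labels)
    data = pd.concat(frames, ignore_index=True)
    labels = None
    if all(lf is not None for lf in label_frames):
        labels = pd.concat(label_frames, ignore_index=True)
    matrix = FeatureMatrix(data, labels=labels, columns=columns)
    return CohortFeatures(
        matrix=matrix, kept_by_sample=kept_by_sample, samples=list(samples)
    )


def summarize_cohort(
    cohort: CohortFeatures,
    posteriors_by_model: Mapping[str, np.ndarray],
    norm_mb: float,
    threshold_tmb: float = 0.5,
) -> list[SampleSummary]:
    """Per-sample TMB (truth/naive/corrected), MVTSM, group, and TPR at the cutoff."""
    meta = cohort.matrix.meta
    labels = cohort.matrix.y
    summaries = []
    for s in cohort.samples:
        mask = (meta["sample_id"] == s.patient_id).to_numpy()
        kept = cohort.kept_by_sample[s.patient_id]
        corrected = {}
        tpr = None
        for model_id, post in posteriors_by_model.items():
            p = np.asarray(post)[mask]
            corrected[model_id] = float(np.sum(p >= threshold_tmb)) / norm_mb
            if labels is not None:
                y = labels[mask]
                n_true = int(np.sum(y == 1))
                if n_true > 0:
                    tpr = float(np.sum((p >= threshold_tmb) & (y == 1)) / n_true)
        tmbs = compute_tmb(kept, None, norm_mb)
        summaries.append(
            SampleSummary(
                sample_id=s.patient_id,
                true_tmb=tmbs["truth"].tmb if "truth" in tmbs else 0.0,
                naive_tmb=tmbs["naive"].tmb,
                corrected_tmb=corrected,
                mvtsm=mvtsm(s, kept=kept),
                group=s.group,
                tpr=tpr,
            )
        )
    return summaries
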