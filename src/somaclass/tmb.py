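"""Tumor mutational burden: naive, model-corrected, and truth estimates.

TMB is the number of kept coding nonsynonymous somatic mutations per
megabase. The naive estimate counts everything that survived filtering; the
corrected estimate keeps only variants the classifier deems somatic at the
TMB posterior cutoff; the truth estimate (when labels exist) counts
truth-somatic kept variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import VariantCall

__all__ = ["TmbEstimate", "footprint_constant", "compute_tmb", "tmb_from_counts"]


@dataclass(frozen=True)
class TmbEstimate:
    sample_id: str
    method: str  # "truth", "naive", or "corrected:<model id>"
    mutation_count: int
    norm_mb: float

    def __post_init__(self) -> None:
        if self.norm_mb <= 0:
            raise ValueError(f"norm_mb must be positive, got {self.norm_mb}")
        if self.mutation_count < 0:
            raise ValueError("mutation_count must be non-negative")

    @property
    def tmb(self) -> float:
        return self.mutation_count / self.norm_mb


def footprint_constant(
    kit_footprints_mb: Sequence[float], patient_counts: Sequence[int]
) -> tuple[float, int]:
    """Patient-weighted average capture-kit footprint, plus its rounded value.

    This is the pooled single-constant normalization mode; with footprints
    (33.0, 37.3, 63.5) MB and patient counts (105, 45, 45) the rounded
    constant is 41.
    """
    if len(kit_footprints_mb) != len(patient_counts):
        raise ValueError(
            f"footprints ({len(kit_footprints_mb)}) and counts "
            f"({len(patient_counts)}) length mismatch"
        )
    f = np.asarray(kit_footprints_mb, dtype=float)
    n = np.asarray(patient_counts, dtype=float)
    if np.any(f <= 0) or np.any(n <= 0):
        raise ValueError("footprints and counts must be positive")
    weighted = float(np.sum(f * n) / np.sum(n))
    return weighted, int(round(weighted))


def tmb_from_counts(
    sample_id: str, method: str, mutation_count: int, norm_mb: float
) -> TmbEstimate:
    return TmbEstimate(sample_id, method, mutation_count, norm_mb)


def compute_tmb(
    kept_variants: Sequence[VariantCall],
    posteriors: np.ndarray | None,
    norm_mb: float,
    threshold_tmb: float = 0.5,
    model_id: str = "model",
) -> dict[str, TmbEstimate]:
    """Per-method TMB for one sample's kept variants.

    Returns a dict with keys ``naive``, ``corrected:<model_id>`` (when
    posteriors are given), and ``truth`` (when all variants carry labels).
    """
    if norm_mb <= 0:
        raise ValueError(f"norm_mb must be positive, got {norm_mb}")
    sample_ids = {v.sample_id for v in kept_variants}
    if len(sample_ids) > 1:
        raise ValueError(f"kept variants span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    out = {
        "naive": TmbEstimate(sample_id, "naive", len(kept_variants), norm_mb)
    }
    if posteriors is not None:
        p = np.asarray(posteriors, dtype=float)
        if len(p) != len(kept_variants):
            raise ValueError("posteriors not aligned to kept variants")
        corrected = int(np.sum(p >= threshold_tmb))
        out[f"corrected:{model_id}"] = TmbEstimate(
            sample_id, f"corrected:{model_id}", corrected, norm_mb
        )
    if kept_variants and all(v.truth_label is not None for v in kept_variants):
        truth = sum(v.truth_label for v in kept_variants)
        out["truth"] = TmbEstimate(sample_id, "truth", int(truth), norm_mb)
    return out


def write_tmb_table(estimates: Sequence[TmbEstimate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmethod\tcount\tnorm_mb\ttmb\n")
        for e in estimates:
            fh.write(
                f"{e.sample_id}\t{e.method}\t{e.mutation_count}\t{e.norm_mb}\t{e.tmb:.6g}\n"
            )
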