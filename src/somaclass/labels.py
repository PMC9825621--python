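"""Somatic/germline truth labels from a matched-normal call set.

A tumor-only kept variant is somatic (1) iff its normalized key appears in
the matched-normal pipeline's somatic call set; everything else the
tumor-only pipeline kept is germline (0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .pon import VariantKey, normalize_key
from .variant_io import VariantCall

__all__ = ["TruthLabel", "label_variants", "attach_labels"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruthLabel:
    key: VariantKey
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def label_variants(
    tumor_only_kept: Sequence[VariantCall],
    matched_somatic_keys: Iterable[VariantKey],
) -> list[TruthLabel]:
    """Label every kept tumor-only variant; coverage is total.

    Matched-normal somatic keys that never appear in the kept set mark a
    sensitivity ceiling of the tumor-only pipeline; they are logged, not
    injected.
    """
    somatic = {normalize_key(*k) for k in matched_somatic_keys}
    labels = []
    seen: set[VariantKey] = set()
    for v in tumor_only_kept:
        key = normalize_key(*v.key)
        seen.add(key)
        labels.append(TruthLabel(key=key, label=int(key in somatic)))
    unmatched = len(somatic - seen)
    if unmatched:
        logger.info(
            "%d matched-normal somatic keys absent from tumor-only kept set",
            unmatched,
        )
    return labels


def attach_labels(
    tumor_only_kept: Sequence[VariantCall],
    matched_somatic_keys: Iterable[VariantKey],
) -> list[VariantCall]:
    """Return copies of the kept variants with ``truth_label`` populated."""
    labels = label_variants(tumor_only_kept, matched_somatic_keys)
    return [v.with_label(t.label) for v, t in zip(tumor_only_kept, labels)]
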