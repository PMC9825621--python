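"""Pre-classification filtering: keep passing, coding, population-rare variants.

Removed variants are dropped from every downstream computation — they are
not counted as true negatives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .variant_io import VariantCall, compute_pop_max

__all__ = ["FilterConfig", "apply_prefilter", "count_to_classify", "RULE_ORDER"]

DEFAULT_ONTOLOGIES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel"}
)

#: Fixed rule evaluation order; the removal log records the first failure.
RULE_ORDER = ("caller_filter", "fpfilter", "ontology", "pop_max")


@dataclass(frozen=True)
class FilterConfig:
    pop_max_threshold: float = 0.01
    allowed_ontologies: frozenset[str] = DEFAULT_ONTOLOGIES
    require_fpfilter_pass: bool = True
    require_caller_pass: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.pop_max_threshold <= 1.0:
            raise ValueError(
                f"pop_max_threshold must be in (0,1], got {self.pop_max_threshold}"
            )
        if not self.allowed_ontologies:
            raise ValueError("allowed_ontologies must be non-empty")
        object.__setattr__(self, "allowed_ontologies", frozenset(self.allowed_ontologies))


def _first_failure(v: VariantCall, cfg: FilterConfig) -> str | None:
    if cfg.require_caller_pass and v.caller_filter != "PASS":
        return "caller_filter"
    if cfg.require_fpfilter_pass and v.fpfilter != "PASS":
        return "fpfilter"
    if v.ontology not in cfg.allowed_ontologies:
        return "ontology"
    # strict inequality: a variant exactly at the threshold is removed
    if compute_pop_max(v.db_freqs) >= cfg.pop_max_threshold:
        return "pop_max"
    return None


def apply_prefilter(
    variants: Sequence[VariantCall], cfg: FilterConfig | None = None
) -> tuple[list[VariantCall], list[tuple[tuple, str]]]:
    """Apply all filter rules; return (kept, removal_log).

    The removal log holds ``(variant key, first failing rule)`` pairs in
    input order, with rules checked in :data:`RULE_ORDER`.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    removal_log: list[tuple[tuple, str]] = []
    for v in variants:
        reason = _first_failure(v, cfg)
        if reason is None:
            kept.append(v)
        else:
            removal_log.append((v.key, reason))
    return kept, removal_log


def count_to_classify(kept: Sequence[VariantCall]) -> dict[str, int]:
    """Per-sample number of variants to classify (the ``count`` feature)."""
    return dict(Counter(v.sample_id for v in kept))


def write_removal_log(removal_log: Sequence[tuple[tuple, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\treason\n")
        for (chrom, pos, ref, alt), reason in removal_log:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{reason}\n")
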