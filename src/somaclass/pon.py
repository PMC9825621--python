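"""Leave-one-out variant-level panels of normals.

A panel for patient *p* is built from the normal samples of every *other*
patient; any variant key seen in at least two of those retained normals
joins the panel and is subtracted from *p*'s tumor-only call set.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variant_io import VariantCall

__all__ = [
    "VariantKey",
    "PanelOfNormals",
    "PonLeakageError",
    "normalize_key",
    "build_loo_pon",
    "apply_pon",
    "write_panel",
    "read_panel",
]

VariantKey = tuple[str, int, str, str]

MIN_PANEL_PATIENTS = 3
DEFAULT_RECURRENCE = 2


class PonLeakageError(ValueError):
    """Raised when a panel would be (or is) applied to its excluded patient's data."""


@dataclass(frozen=True)
class PanelOfNormals:
    excluded_patient: str
    member_count: int
    variant_keys: frozenset[VariantKey]


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Left-align-trim an allele pair to its minimal representation.

    Shared suffix bases are removed first, then shared prefix bases (advancing
    the position), mirroring bcftools norm semantics for already-left-aligned
    indels. At least one base is kept on each allele.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def build_loo_pon(
    normal_variant_sets: Mapping[str, Iterable[VariantKey]],
    leave_out: str,
    min_recurrence: int = DEFAULT_RECURRENCE,
) -> PanelOfNormals:
    """Build the leave-one-out panel for one patient.

    Parameters
    ----------
    normal_variant_sets
        Map patient id -> variant keys called in that patient's normal sample.
    leave_out
        The patient whose normal is excluded from the panel.
    min_recurrence
        Minimum number of retained normals a key must appear in (default 2,
        matching the published rule; exposed for experimentation only).
    """
    if leave_out not in normal_variant_sets:
        raise KeyError(f"leave_out patient {leave_out!r} not in normal sets")
    if len(normal_variant_sets) < MIN_PANEL_PATIENTS:
        raise ValueError(
            f"need >= {MIN_PANEL_PATIENTS} patients for a leave-one-out panel, "
            f"got {len(normal_variant_sets)}"
        )
    counts: Counter[VariantKey] = Counter()
    members = 0
    for patient, keys in normal_variant_sets.items():
        if patient == leave_out:
            continue
        members += 1
        counts.update(set(keys))
    panel_keys = frozenset(k for k, n in counts.items() if n >= min_recurrence)
    return PanelOfNormals(
        excluded_patient=leave_out, member_count=members, variant_keys=panel_keys
    )


def apply_pon(
    variants: Sequence[VariantCall], panel: PanelOfNormals
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition variants into (kept, removed) by panel membership.

    Raises :class:`PonLeakageError` when the variants belong to the patient
    the panel was built for exclusion of — i.e. a panel/sample mismatch that
    would leak the patient's own germline into filtering.
    """
    for v in variants:
        if v.sample_id.split(":")[0] != panel.excluded_patient:
            raise PonLeakageError(
                f"panel excludes patient {panel.excluded_patient!r} but got "
                f"variants from {v.sample_id!r}"
            )
    kept, removed = [], []
    for v in variants:
        key = normalize_key(*v.key)
        (removed if key in panel.variant_keys else kept).append(v)
    return kept, removed


def write_panel(panel: PanelOfNormals, vcf_path: str, meta_path: str) -> None:
    """Write a sites-only VCF plus a JSON sidecar with member metadata."""
    contigs = sorted({k[0] for k in panel.variant_keys})
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(panel.variant_keys):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "excluded_patient": panel.excluded_patient,
                "member_count": panel.member_count,
                "n_sites": len(panel.variant_keys),
            },
            fh,
            indent=2,
        )


def read_panel(vcf_path: str, meta_path: str) -> PanelOfNormals:
    with open(meta_path) as fh:
        meta = json.load(fh)
    keys: set[VariantKey] = set()
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt = line.split("\t")[:5]
            keys.add((chrom, int(pos) - 1, ref, alt))
    return PanelOfNormals(
        excluded_patient=meta["excluded_patient"],
        member_count=meta["member_count"],
        variant_keys=frozenset(keys),
    )
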