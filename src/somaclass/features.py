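"""Model-ready feature engineering.

Each kept variant becomes one row of a fixed, versioned schema:

* 5 scalars — ``pop_max``, ``count`` (sample-level, broadcast),
  ``t_alt_freq``, ``t_maj_allele``, ``max_cosmic_count``;
* 20 copy-number-aware histogram bins — ``snp_vaf_bin_00`` .. ``snp_vaf_bin_19``,
  counting informative SNPs (common heterozygous germline SNPs) in the
  variant's copy-number segment whose VAF falls in [i/20, (i+1)/20);
* 4 ontology one-hot columns;
* 7 pyrimidine-centered substitution-class columns (6 classes + non-SBS);
* 17 flanking-context columns (16 5'x3' flank pairs + non-SBS-y).
"""

from __future__ import annotations

import hashlib
import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import NON_SBS, CopyNumberSegment, VariantCall, compute_pop_max

__all__ = [
    "SCHEMA_VERSION",
    "FEATURE_COLUMNS",
    "N_VAF_BINS",
    "InformativeSnp",
    "FeatureMatrix",
    "schema_hash",
    "collect_informative_snps",
    "snp_vaf_histogram",
    "substitution_encoding",
    "assemble_feature_matrix",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
N_VAF_BINS = 20

SCALAR_COLUMNS = ["pop_max", "count", "t_alt_freq", "t_maj_allele", "max_cosmic_count"]
VAF_BIN_COLUMNS = [f"snp_vaf_bin_{i:02d}" for i in range(N_VAF_BINS)]
ONTOLOGY_COLUMNS = ["missense", "nonsense", "frameshift_indel", "inframe_indel"]
SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
SUBSTITUTION_COLUMNS = [f"sub_{c.replace('>', '_')}" for c in SUBSTITUTION_CLASSES] + [
    "non_SBS"
]
_BASES = "ACGT"
CONTEXT_PAIRS = [five + three for five in _BASES for three in _BASES]
CONTEXT_COLUMNS = [f"ctx_{p}" for p in CONTEXT_PAIRS] + ["non_SBS_y"]

FEATURE_COLUMNS = (
    SCALAR_COLUMNS
    + VAF_BIN_COLUMNS
    + ONTOLOGY_COLUMNS
    + SUBSTITUTION_COLUMNS
    + CONTEXT_COLUMNS
)

META_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "variant_category"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Informative-SNP eligibility: common in germline databases, confidently
#: called, and heterozygous by VAF window (copy number shifts het VAFs off 0.5).
COMMON_POP_MAX = 0.01
HET_VAF_WINDOW = (0.05, 0.95)


def schema_hash(columns: Sequence[str] = FEATURE_COLUMNS) -> str:
    payload = (SCHEMA_VERSION + "\n" + "\n".join(columns)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class InformativeSnp:
    """A common heterozygous germline SNP informing local copy number."""

    chrom: str
    pos: int
    vaf: float
    pop_max: float
    segment_id: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.pop_max < COMMON_POP_MAX:
            raise ValueError(
                f"informative SNP must be common (pop_max >= {COMMON_POP_MAX})"
            )


class FeatureMatrix:
    """A feature table with a versioned schema and truth-label alignment."""

    def __init__(
        self,
        data: pd.DataFrame,
        labels: pd.Series | None = None,
        columns: Sequence[str] = FEATURE_COLUMNS,
    ):
        missing = [c for c in list(columns) + META_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing}")
        self.columns = list(columns)
        self.data = data.reset_index(drop=True)
        self.schema_hash = schema_hash(self.columns)
        if labels is not None and len(labels) != len(data):
            raise ValueError("labels not aligned to feature rows")
        self.labels = None if labels is None else labels.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray | None:
        return None if self.labels is None else self.labels.to_numpy(dtype=int)

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[META_COLUMNS]

    def append(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if other.schema_hash != self.schema_hash:
            ours, theirs = set(self.columns), set(other.columns)
            raise ValueError(
                "schema mismatch when appending cohorts; differing columns: "
                f"{sorted(ours ^ theirs)}"
            )
        data = pd.concat([self.data, other.data], ignore_index=True)
        labels = None
        if self.labels is not None and other.labels is not None:
            labels = pd.concat([self.labels, other.labels], ignore_index=True)
        return FeatureMatrix(data, labels=labels, columns=self.columns)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#somaclass-features\tv{SCHEMA_VERSION}\t{self.schema_hash}\n")
            cols = META_COLUMNS + self.columns
            out = self.data[cols].copy()
            if self.labels is not None:
                out["truth_label"] = self.labels.values
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureMatrix":
        with open(path) as fh:
            magic = fh.readline().rstrip("\n").split("\t")
            if magic[0] != "#somaclass-features":
                raise ValueError(f"{path}: not a feature matrix TSV")
            data = pd.read_csv(fh, sep="\t")
        labels = None
        if "truth_label" in data.columns:
            labels = data.pop("truth_label")
        feat_cols = [c for c in data.columns if c not in META_COLUMNS]
        fm = cls(data, labels=labels, columns=feat_cols)
        if magic[2] != fm.schema_hash:
            raise ValueError(
                f"{path}: stored schema hash {magic[2]} != recomputed {fm.schema_hash}"
            )
        return fm


# ---------------------------------------------------------------------------
# Informative SNPs and VAF histograms
# ---------------------------------------------------------------------------

class _SegmentIndex:
    """Locate the segment containing a position, per chromosome."""

    def __init__(self, segments: Sequence[CopyNumberSegment]):
        self.by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        ordered = sorted(range(len(segments)), key=lambda i: (segments[i].chrom, segments[i].start))
        for idx in ordered:
            s = segments[idx]
            starts, ends, ids = self.by_chrom.setdefault(s.chrom, ([], [], []))
            if starts and s.start < ends[-1]:
                raise ValueError(
                    f"overlapping segments on {s.chrom} at {s.start}"
                )
            starts.append(s.start)
            ends.append(s.end)
            ids.append(idx)

    def find(self, chrom: str, pos: int) -> int | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return ids[i]
        return None


def collect_informative_snps(
    sample_variants: Sequence[VariantCall],
    segments: Sequence[CopyNumberSegment],
) -> list[InformativeSnp]:
    """Select common heterozygous germline SNVs and pin each to its segment.

    Input should be the *full* call set for the sample (common and non-coding
    variants included) — the prefilter deliberately removes exactly the
    common SNPs this operation needs.
    """
    index = _SegmentIndex(segments)
    snps: list[InformativeSnp] = []
    lo, hi = HET_VAF_WINDOW
    for v in sample_variants:
        if v.variant_class != "SNV" or v.fpfilter != "PASS":
            continue
        pm = compute_pop_max(v.db_freqs)
        if pm < COMMON_POP_MAX:
            continue
        if not lo < v.t_alt_freq < hi:
            continue
        seg = index.find(v.chrom, v.pos)
        if seg is None:
            continue
        snps.append(
            InformativeSnp(
                chrom=v.chrom, pos=v.pos, vaf=v.t_alt_freq, pop_max=pm, segment_id=seg
            )
        )
    return snps


def _bin_vaf(vaf: float) -> int:
    """Histogram bin for a VAF: [i/20, (i+1)/20), with 1.0 clamped to bin 19."""
    return min(int(vaf * N_VAF_BINS), N_VAF_BINS - 1)


def _segment_histograms(snps: Sequence[InformativeSnp]) -> dict[int, np.ndarray]:
    hists: dict[int, np.ndarray] = {}
    for s in snps:
        h = hists.get(s.segment_id)
        if h is None:
            h = hists[s.segment_id] = np.zeros(N_VAF_BINS, dtype=np.int64)
        h[_bin_vaf(s.vaf)] += 1
    return hists


def snp_vaf_histogram(
    variant: VariantCall,
    snps: Sequence[InformativeSnp],
    segments: Sequence[CopyNumberSegment],
) -> np.ndarray:
    """20-bin count histogram of informative-SNP VAFs in the variant's segment.

    Variants outside all segments get an all-zero histogram (logged).
    """
    index = _SegmentIndex(segments)
    seg = index.find(variant.chrom, variant.pos)
    if seg is None:
        logger.warning(
            "variant %s:%d lies in no copy-number segment; zero histogram",
            variant.chrom,
            variant.pos,
        )
        return np.zeros(N_VAF_BINS, dtype=np.int64)
    hist = np.zeros(N_VAF_BINS, dtype=np.int64)
    for s in snps:
        if s.segment_id == seg:
            hist[_bin_vaf(s.vaf)] += 1
    return hist


# ---------------------------------------------------------------------------
# Mutational-spectrum encoding
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_encoding(ref: str, alt: str, tri_context: str) -> tuple[str, str]:
    """Pyrimidine-centered substitution class and flanking-base pair.

    Purine-centered substitutions are reverse-complemented so every SNV maps
    onto one of the six canonical classes. Non-SNVs return
    ``("NON_SBS", "NON_SBS_Y")``.
    """
    if len(ref) != 1 or len(alt) != 1:
        return ("NON_SBS", "NON_SBS_Y")
    if tri_context == NON_SBS:
        raise ValueError("SNV requires a trinucleotide context")
    if len(tri_context) != 3 or tri_context[1] != ref:
        raise ValueError(
            f"tri_context {tri_context!r} does not center on ref allele {ref!r}"
        )
    if ref in "AG":  # purine-centered: flip strand
        ref, alt = _revcomp(ref), _revcomp(alt)
        tri_context = _revcomp(tri_context)
    klass = f"{ref}>{alt}"
    if klass not in SUBSTITUTION_CLASSES:
        raise ValueError(f"invalid substitution {klass}")
    return klass, tri_context[0] + tri_context[2]


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def assemble_feature_matrix(
    kept_variants: Sequence[VariantCall],
    snps: Sequence[InformativeSnp],
    segments: Sequence[CopyNumberSegment],
    counts: Mapping[str, int],
) -> FeatureMatrix:
    """Build one schema-conformant row per kept variant.

    Rows are sorted deterministically by (sample_id, chrom, pos, ref, alt).
    ``counts`` must come from ``count_to_classify`` over the same kept set.
    """
    index = _SegmentIndex(segments)
    seg_hists = _segment_histograms(snps)
    zero_hist = np.zeros(N_VAF_BINS, dtype=np.int64)

    ordered = sorted(kept_variants, key=lambda v: (v.sample_id, v.chrom, v.pos, v.ref, v.alt))
    rows = []
    labels: list[int] = []
    have_labels = all(v.truth_label is not None for v in ordered)
    n_unsegmented = 0
    for v in ordered:
        seg = index.find(v.chrom, v.pos)
        if seg is None:
            n_unsegmented += 1
            hist = zero_hist
        else:
            hist = seg_hists.get(seg, zero_hist)
        if v.variant_class == "SNV":
            sub_class, ctx = substitution_encoding(v.ref, v.alt, v.tri_context)
        else:
            sub_class, ctx = "NON_SBS", "NON_SBS_Y"

        row = {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "variant_category": "SNV" if v.variant_class == "SNV" else "indel",
            "pop_max": compute_pop_max(v.db_freqs),
            "count": counts.get(v.sample_id, 0),
            "t_alt_freq": v.t_alt_freq,
            "t_maj_allele": v.t_maj_allele,
            "max_cosmic_count": v.cosmic_count,
        }
        for i, col in enumerate(VAF_BIN_COLUMNS):
            row[col] = int(hist[i])
        for col in ONTOLOGY_COLUMNS:
            row[col] = int(v.ontology == col)
        for klass, col in zip(SUBSTITUTION_CLASSES, SUBSTITUTION_COLUMNS):
            row[col] = int(sub_class == klass)
        row["non_SBS"] = int(sub_class == "NON_SBS")
        for pair, col in zip(CONTEXT_PAIRS, CONTEXT_COLUMNS):
            row[col] = int(ctx == pair)
        row["non_SBS_y"] = int(ctx == "NON_SBS_Y")
        rows.append(row)
        if have_labels:
            labels.append(int(v.truth_label))  # type: ignore[arg-type]

    if n_unsegmented:
        logger.warning(
            "%d variants outside all copy-number segments (zero histograms)",
            n_unsegmented,
        )
    data = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
    lab = pd.Series(labels, dtype=int) if have_labels else None
    return FeatureMatrix(data, labels=lab)
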