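"""Readers, writers, and domain types for the variant-level file formats.

Internal coordinates are 0-based half-open everywhere; VCF positions are
converted on read and restored on write. A small versioned TSV interchange
format is provided for lossless round-tripping of annotated variant tables
between pipeline stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "NON_SBS",
    "DEFAULT_DATABASES",
    "VariantCall",
    "CopyNumberSegment",
    "CaptureFootprint",
    "VariantParseError",
    "compute_pop_max",
    "read_annotated_variants",
    "read_segments",
    "read_footprint",
    "merge_intervals",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_variants_vcf",
]

#: Sentinel for variants without a single-base trinucleotide context.
NON_SBS = "NON_SBS"

#: Default germline population-frequency database fields (dbNSFP-style names).
DEFAULT_DATABASES = (
    "1000Gp3_AF",
    "TWINSUK_AF",
    "ALSPAC_AF",
    "UK10K_AF",
    "ExAC_AC",
    "ExAC_AF",
    "gnomAD_exomes_AF",
    "gnomAD_genomes_AF",
)

VARIANT_CLASSES = ("SNV", "insertion", "deletion", "MNV")
ONTOLOGIES = ("missense", "nonsense", "frameshift_indel", "inframe_indel", "other")

TSV_FORMAT_VERSION = "1"


class VariantParseError(ValueError):
    """Raised when an input file cannot be parsed into domain types."""


def classify_alleles(ref: str, alt: str) -> str:
    """Classify a (ref, alt) allele pair into SNV / insertion / deletion / MNV."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    return "MNV"


@dataclass(frozen=True)
class VariantCall:
    """One annotated tumor-only variant call (single alternate allele)."""

    sample_id: str
    chrom: str
    pos: int  # 0-based start of the REF allele
    ref: str
    alt: str
    variant_class: str
    t_alt_freq: float
    t_maj_allele: float
    depth: int
    caller_filter: str = "PASS"
    fpfilter: str = "PASS"
    ontology: str = "other"
    db_freqs: Mapping[str, float] = field(default_factory=dict)
    cosmic_count: int = 0
    tri_context: str = NON_SBS
    truth_label: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_alt_freq <= 1.0:
            raise ValueError(f"t_alt_freq out of [0,1]: {self.t_alt_freq}")
        if not 0.0 <= self.t_maj_allele <= 1.0:
            raise ValueError(f"t_maj_allele out of [0,1]: {self.t_maj_allele}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class: {self.variant_class}")
        if self.ontology not in ONTOLOGIES:
            raise ValueError(f"unknown ontology: {self.ontology}")
        if self.cosmic_count < 0:
            raise ValueError(f"negative cosmic_count: {self.cosmic_count}")
        if (self.variant_class == "SNV") != (len(self.ref) == 1 and len(self.alt) == 1):
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )
        if (self.variant_class == "SNV") == (self.tri_context == NON_SBS):
            raise ValueError(
                f"tri_context {self.tri_context!r} inconsistent with "
                f"variant_class {self.variant_class!r}"
            )
        if self.truth_label is not None and self.truth_label not in (0, 1):
            raise ValueError(f"truth_label must be 0 or 1, got {self.truth_label}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact variant identity (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pop_max(self) -> float:
        return compute_pop_max(self.db_freqs)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def with_label(self, label: int) -> "VariantCall":
        return replace(self, truth_label=label)


@dataclass(frozen=True)
class CopyNumberSegment:
    """A genomic interval with a log2 copy-ratio for one sample (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_bins: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.n_bins <= 0:
            raise ValueError(f"n_bins must be positive, got {self.n_bins}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class CaptureFootprint:
    """Merged capture-kit target intervals and their total size in megabases."""

    kit_name: str
    intervals: tuple[tuple[str, int, int], ...]
    footprint_mb: float


def compute_pop_max(db_freqs: Mapping[str, float]) -> float:
    """Maximum population allele frequency across the germline databases.

    A variant absent from every database is maximally rare and scores 0.0.
    """
    best = 0.0
    for name, freq in db_freqs.items():
        if freq is None:
            continue
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"database frequency out of [0,1]: {name}={freq}")
        best = max(best, float(freq))
    return best


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

#: INFO keys used in the package's annotated VCFs. Database AF fields carry a
#: dbNSFP_ prefix because raw dbNSFP names may start with a digit, which VCF
#: INFO identifiers do not allow.
INFO_ONTOLOGY = "ONTOLOGY"
INFO_FPFILTER = "FPFILTER"
INFO_COSMIC = "COSMIC_CNT"
INFO_TRI_CONTEXT = "TRI_CONTEXT"
DB_INFO_PREFIX = "dbNSFP_"


def _db_info_key(db_name: str) -> str:
    return DB_INFO_PREFIX + db_name


def read_annotated_variants(
    path: str,
    sample_id: str,
    databases: Sequence[str] = DEFAULT_DATABASES,
) -> list[VariantCall]:
    """Read an annotated VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one call per alternate allele;
    ``t_maj_allele`` is computed over all alleles of the original record.
    Missing annotations degrade gracefully (no db entries, cosmic 0,
    ontology "other").
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VariantParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    out: list[VariantCall] = []
    with vcf:
        for rec in vcf:
            out.extend(_record_to_calls(rec, sample_id, databases))
    return out


def _record_to_calls(
    rec: "pysam.VariantRecord", sample_id: str, databases: Sequence[str]
) -> list[VariantCall]:
    if not rec.alts:
        return []
    ad = None
    if rec.samples:
        fmt = rec.samples[0]
        ad = fmt.get("AD")
    if ad is None or any(a is None for a in ad):
        raise VariantParseError(
            f"record {rec.chrom}:{rec.pos} {rec.ref}>{','.join(rec.alts)} "
            "lacks the AD genotype depth field"
        )
    depth = int(sum(ad))
    maj = max(ad) / depth if depth > 0 else 0.0

    def info_get(key, default=None):
        # pysam raises for keys absent from the header; treat as missing
        try:
            val = rec.info.get(key, default)
        except (KeyError, ValueError):
            return default
        return default if val is None else val

    ontology = str(info_get(INFO_ONTOLOGY, "other"))
    if ontology not in ONTOLOGIES:
        ontology = "other"
    fpfilter = str(info_get(INFO_FPFILTER, "PASS"))
    caller_filter = ";".join(rec.filter.keys()) if list(rec.filter.keys()) else "PASS"
    cosmic = int(info_get(INFO_COSMIC, 0))
    tri = str(info_get(INFO_TRI_CONTEXT, NON_SBS))
    db_freqs: dict[str, float] = {}
    for db in databases:
        val = info_get(_db_info_key(db))
        if val is not None:
            if isinstance(val, tuple):
                val = val[0]
            db_freqs[db] = float(val)

    calls = []
    for i, alt in enumerate(rec.alts):
        alt_reads = ad[i + 1] if i + 1 < len(ad) else 0
        vclass = classify_alleles(rec.ref, alt)
        calls.append(
            VariantCall(
                sample_id=sample_id,
                chrom=rec.chrom,
                pos=rec.pos - 1,  # VCF is 1-based
                ref=rec.ref,
                alt=alt,
                variant_class=vclass,
                t_alt_freq=alt_reads / depth if depth > 0 else 0.0,
                t_maj_allele=maj,
                depth=depth,
                caller_filter=caller_filter,
                fpfilter=fpfilter,
                ontology=ontology,
                db_freqs=db_freqs,
                cosmic_count=cosmic,
                tri_context=tri if vclass == "SNV" else NON_SBS,
            )
        )
    return calls


_VCF_HEADER_LINES = [
    f'##INFO=<ID={INFO_ONTOLOGY},Number=1,Type=String,Description="Variant consequence ontology">',
    f'##INFO=<ID={INFO_FPFILTER},Number=1,Type=String,Description="Artifact filter status">',
    f'##INFO=<ID={INFO_COSMIC},Number=1,Type=Integer,Description="COSMIC occurrence count">',
    f'##INFO=<ID={INFO_TRI_CONTEXT},Number=1,Type=String,Description="Reference trinucleotide context">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
]


def write_variants_vcf(
    variants: Sequence[VariantCall],
    path: str,
    sample_id: str | None = None,
    databases: Sequence[str] = DEFAULT_DATABASES,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write VariantCalls to an uncompressed annotated VCF (one sample column)."""
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for db in databases:
        header.add_line(
            f'##INFO=<ID={_db_info_key(db)},Number=1,Type=Float,'
            f'Description="Population AF from {db}">'
        )
    if contigs is None:
        contigs = sorted({v.chrom for v in variants})
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    header.filters.add("REJECT", None, None, "Failed caller filters")
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else "SAMPLE"
    header.add_sample(sample_id)

    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos, alleles=(v.ref, v.alt)
            )
            rec.filter.add("PASS" if v.caller_filter == "PASS" else "REJECT")
            rec.info[INFO_ONTOLOGY] = v.ontology
            rec.info[INFO_FPFILTER] = v.fpfilter
            rec.info[INFO_COSMIC] = v.cosmic_count
            if v.variant_class == "SNV":
                rec.info[INFO_TRI_CONTEXT] = v.tri_context
            for db, freq in v.db_freqs.items():
                rec.info[_db_info_key(db)] = float(freq)
            alt_reads = int(round(v.t_alt_freq * v.depth))
            rec.samples[sample_id]["AD"] = (v.depth - alt_reads, alt_reads)
            rec.samples[sample_id]["DP"] = v.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# SEG / BED
# ---------------------------------------------------------------------------

def read_segments(path: str, sample_id: str = "", one_based: bool = False) -> list[CopyNumberSegment]:
    """Read a tab-delimited segment file with columns chrom, start, end, log2.

    A header row is detected and skipped. ``one_based=True`` treats input
    starts as 1-based inclusive (SEG convention) and converts to 0-based
    half-open.
    """
    segs: list[CopyNumberSegment] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if line_no == 1 and not _is_number(parts[1] if len(parts) > 1 else ""):
                continue  # header
            if len(parts) < 4:
                raise VariantParseError(
                    f"{path}:{line_no}: expected >=4 columns, got {len(parts)}"
                )
            chrom, start_s, end_s, log2_s = parts[:4]
            try:
                start, end, log2 = int(start_s), int(end_s), float(log2_s)
            except ValueError as exc:
                raise VariantParseError(f"{path}:{line_no}: {exc}") from exc
            if one_based:
                start -= 1
            segs.append(
                CopyNumberSegment(
                    sample_id=sample_id, chrom=chrom, start=start, end=end,
                    log2_ratio=log2,
                )
            )
    segs.sort(key=lambda s: (s.chrom, s.start))
    validate_non_overlapping(segs)
    return segs


def validate_non_overlapping(segments: Iterable[CopyNumberSegment]) -> None:
    """Raise if any two same-sample, same-chromosome segments overlap."""
    ordered = sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping segments {a.chrom}:{a.start}-{a.end} and "
                f"{b.chrom}:{b.start}-{b.end}"
            )


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Merge possibly-overlapping 0-based half-open intervals."""
    by_chrom: list[tuple[str, int, int]] = sorted(intervals)
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in by_chrom:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def read_footprint(path: str, kit_name: str = "") -> CaptureFootprint:
    """Read a BED3+ target file, merge intervals, and compute the footprint."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VariantParseError(
                    f"{path}:{line_no}: BED needs >=3 columns, got {len(parts)}"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{line_no}: end {end} <= start {start}")
            intervals.append((chrom, start, end))
    merged = merge_intervals(intervals)
    total = sum(e - s for _, s, e in merged)
    if total == 0:
        warnings.warn(f"empty capture footprint in {path}", stacklevel=2)
    return CaptureFootprint(
        kit_name=kit_name or path, intervals=tuple(merged), footprint_mb=total / 1e6
    )


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
    "t_alt_freq", "t_maj_allele", "depth", "caller_filter", "fpfilter",
    "ontology", "db_freqs", "cosmic_count", "tri_context", "truth_label",
]


def write_variants_tsv(variants: Sequence[VariantCall], path: str) -> None:
    """Write variants to the versioned TSV interchange format (lossless)."""
    with open(path, "w") as fh:
        fh.write(f"#somaclass-variants\tv{TSV_FORMAT_VERSION}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for v in variants:
            dbs = ";".join(
                f"{k}={v.db_freqs[k]!r}" for k in sorted(v.db_freqs)
            )
            row = [
                v.sample_id, v.chrom, str(v.pos), v.ref, v.alt, v.variant_class,
                repr(v.t_alt_freq), repr(v.t_maj_allele), str(v.depth),
                v.caller_filter, v.fpfilter, v.ontology, dbs or ".",
                str(v.cosmic_count), v.tri_context,
                "." if v.truth_label is None else str(v.truth_label),
            ]
            fh.write("\t".join(row) + "\n")


def read_variants_tsv(path: str) -> list[VariantCall]:
    """Read the TSV interchange format written by :func:`write_variants_tsv`."""
    out: list[VariantCall] = []
    with open(path) as fh:
        magic = fh.readline().rstrip("\n").split("\t")
        if not magic or magic[0] != "#somaclass-variants":
            raise VariantParseError(f"{path}: missing interchange format header")
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise VariantParseError(f"{path}: unexpected column header")
        for line_no, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise VariantParseError(
                    f"{path}:{line_no}: expected {len(_TSV_COLUMNS)} fields"
                )
            rec = dict(zip(_TSV_COLUMNS, parts))
            db_freqs = {}
            if rec["db_freqs"] != ".":
                for item in rec["db_freqs"].split(";"):
                    k, _, val = item.partition("=")
                    db_freqs[k] = float(val)
            out.append(
                VariantCall(
                    sample_id=rec["sample_id"],
                    chrom=rec["chrom"],
                    pos=int(rec["pos"]),
                    ref=rec["ref"],
                    alt=rec["alt"],
                    variant_class=rec["variant_class"],
                    t_alt_freq=float(rec["t_alt_freq"]),
                    t_maj_allele=float(rec["t_maj_allele"]),
                    depth=int(rec["depth"]),
                    caller_filter=rec["caller_filter"],
                    fpfilter=rec["fpfilter"],
                    ontology=rec["ontology"],
                    db_freqs=db_freqs,
                    cosmic_count=int(rec["cosmic_count"]),
                    tri_context=rec["tri_context"],
                    truth_label=None if rec["truth_label"] == "." else int(rec["truth_label"]),
                )
            )
    return out


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
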