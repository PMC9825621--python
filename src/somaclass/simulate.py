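"""Synthetic tumor-only cohorts with truth labels.

Each simulated patient carries:

* copy-number segments tiling a small multi-chromosome exome, with log2
  ratios consistent with a drawn purity and per-segment tumor copy number;
* clonal/subclonal somatic mutations whose expected VAF follows standard
  allele-fraction accounting, observed through binomial read sampling;
* rare germline variants (het/hom) whose population-database representation
  depends on the patient's ancestry group — under-represented groups leak
  more rare germline variants past the population-frequency prefilter;
* common heterozygous SNPs that act as informative SNPs for the local
  copy-number VAF histogram;
* somatic/germline differences in mutational spectrum, ontology, and
  COSMIC occurrence counts.

All randomness flows from one seed through per-patient child streams, so
cohorts are bit-reproducible and independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .variant_io import (
    NON_SBS,
    CopyNumberSegment,
    VariantCall,
    write_variants_tsv,
    write_variants_vcf,
)

__all__ = [
    "AncestryGroup",
    "SubtypeSpec",
    "CohortConfig",
    "SimulatedSample",
    "expected_vaf",
    "simulate_cohort",
    "mvtsm",
    "write_sample",
]

_BASES = "ACGT"
_ONTOLOGY_NAMES = ("missense", "nonsense", "frameshift_indel", "inframe_indel", "other")


def expected_vaf(
    purity: float, tumor_copy_number: int, mutant_copies: int, germline: bool = False
) -> float:
    """Expected allele fraction of a variant in a bulk tumor sample.

    Somatic: rho*m / (rho*C_t + 2*(1-rho)). A germline heterozygous variant
    additionally contributes one copy from each contaminating normal cell:
    (rho*m + (1-rho)) / (rho*C_t + 2*(1-rho)).
    """
    rho, c_t, m = purity, tumor_copy_number, mutant_copies
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {rho}")
    if c_t < 1:
        raise ValueError(f"tumor copy number must be >= 1, got {c_t}")
    if not 1 <= m <= c_t:
        raise ValueError(f"mutant copies {m} outside [1, {c_t}]")
    denom = rho * c_t + 2.0 * (1.0 - rho)
    num = rho * m + ((1.0 - rho) if germline else 0.0)
    return num / denom


@dataclass(frozen=True)
class AncestryGroup:
    """An ancestry group's cohort fraction and database representation.

    ``r_db`` is the probability that a group-specific germline variant is
    represented in the population databases (and therefore caught by the
    population-frequency prefilter).
    """

    fraction: float
    r_db: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_db <= 1.0:
            raise ValueError(f"r_db must be in [0,1], got {self.r_db}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0,1], got {self.fraction}")


@dataclass(frozen=True)
class SubtypeSpec:
    """Patient count and true-TMB range (mutations/Mb, uniform) for a subtype."""

    n_patients: int
    tmb_range: tuple[float, float]


@dataclass
class CohortConfig:
    subtypes: dict[str, SubtypeSpec] = field(
        default_factory=lambda: {
            "lowtmb": SubtypeSpec(10, (0.5, 3.0)),
            "midtmb": SubtypeSpec(10, (2.0, 8.0)),
            "hightmb": SubtypeSpec(10, (6.0, 20.0)),
        }
    )
    ancestry_groups: dict[str, AncestryGroup] = field(
        default_factory=lambda: {
            "grpA": AncestryGroup(fraction=0.8, r_db=0.995),
            "grpB": AncestryGroup(fraction=0.2, r_db=0.85),
        }
    )
    purity_range: tuple[float, float] = (0.3, 0.7)
    exome_mb: float = 30.0
    mean_depth: int = 100
    n_chromosomes: int = 8
    max_segments_per_chromosome: int = 3
    # germline architecture
    rare_germline_range: tuple[int, int] = (100, 500)
    ancestry_site_mean: int = 400
    common_snp_per_mb: float = 25.0
    common_carrier_prob: float = 0.35
    rare_pool_size: int = 50_000
    ancestry_pool_size: int = 40_000
    hom_fraction: float = 0.12
    # somatic architecture
    subclonal_fraction: float = 0.15
    ccf_range: tuple[float, float] = (0.25, 0.7)
    # annotation distributions (somatic, germline) where paired
    cosmic_p_nonzero: tuple[float, float] = (0.25, 0.12)
    cosmic_geom_p: float = 0.4
    spectrum_somatic: tuple[float, ...] = (0.20, 0.08, 0.40, 0.07, 0.15, 0.10)
    spectrum_germline: tuple[float, ...] = (0.10, 0.10, 0.28, 0.08, 0.32, 0.12)
    ontology_somatic: tuple[float, ...] = (0.62, 0.12, 0.06, 0.04, 0.16)
    ontology_germline: tuple[float, ...] = (0.62, 0.055, 0.045, 0.08, 0.20)
    indel_fraction: tuple[float, float] = (0.10, 0.10)
    # sequencing / calling
    min_alt_reads: int = 3
    artifact_fraction: float = 0.02
    normal_detection_prob: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 < self.purity_range[0] <= self.purity_range[1] <= 1.0:
            raise ValueError(f"invalid purity range {self.purity_range}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if abs(sum(g.fraction for g in self.ancestry_groups.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry group fractions must sum to 1")
        for name, probs in (
            ("spectrum_somatic", self.spectrum_somatic),
            ("spectrum_germline", self.spectrum_germline),
            ("ontology_somatic", self.ontology_somatic),
            ("ontology_germline", self.ontology_germline),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")

    @property
    def n_patients(self) -> int:
        return sum(s.n_patients for s in self.subtypes.values())

    @property
    def chrom_length(self) -> int:
        return int(self.exome_mb * 1e6 / self.n_chromosomes)

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_yaml(self, path: str) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(_tuples_to_lists(raw), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["subtypes"] = {
            k: SubtypeSpec(v["n_patients"], tuple(v["tmb_range"]))
            for k, v in raw.get("subtypes", {}).items()
        }
        raw["ancestry_groups"] = {
            k: AncestryGroup(**v) for k, v in raw.get("ancestry_groups", {}).items()
        }
        for key in (
            "purity_range", "rare_germline_range", "ccf_range",
            "cosmic_p_nonzero", "indel_fraction",
            "spectrum_somatic", "spectrum_germline",
            "ontology_somatic", "ontology_germline",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


@dataclass
class SimulatedSample:
    """Full tumor-only inputs plus ground truth for one simulated patient."""

    patient_id: str
    subtype: str
    group: str
    purity: float
    true_tmb_rate: float
    variants: list[VariantCall]
    segments: list[CopyNumberSegment]
    normal_keys: frozenset[tuple]
    somatic_keys: frozenset[tuple]

    @property
    def sample_id(self) -> str:
        return self.patient_id


# ---------------------------------------------------------------------------
# Population-level site pools (shared across the cohort)
# ---------------------------------------------------------------------------

class _SitePool:
    """Positions, alleles, context, and indel identity for a pool of sites."""

    def __init__(
        self, rng: np.random.Generator, n: int, cfg: CohortConfig, indel_prob: float
    ):
        total_len = cfg.n_chromosomes * cfg.chrom_length
        flat = rng.integers(0, total_len, size=n)
        self.chrom_idx = flat // cfg.chrom_length
        self.pos = flat % cfg.chrom_length
        self.ref_idx = rng.integers(0, 4, size=n)
        shift = rng.integers(1, 4, size=n)
        self.alt_idx = (self.ref_idx + shift) % 4
        self.flank5 = rng.integers(0, 4, size=n)
        self.flank3 = rng.integers(0, 4, size=n)
        self.is_indel = rng.random(n) < indel_prob
        self.n = n


def _draw_cosmic(
    rng: np.random.Generator, n: int, p_nonzero: float, geom_p: float
) -> np.ndarray:
    nonzero = rng.random(n) < p_nonzero
    counts = np.zeros(n, dtype=np.int64)
    counts[nonzero] = rng.geometric(geom_p, size=int(nonzero.sum()))
    return counts


def _spectrum_alleles(
    rng: np.random.Generator, n: int, spectrum: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (ref, alt, flank5, flank3) base indices from a substitution spectrum."""
    klass = rng.choice(6, size=n, p=np.asarray(spectrum))
    ref = np.where(klass < 3, 1, 3)  # pyrimidine centers: C=1, T=3
    alt_map_c = np.array([0, 2, 3])  # C>A, C>G, C>T
    alt_map_t = np.array([0, 1, 2])  # T>A, T>C, T>G
    alt = np.where(
        klass < 3, alt_map_c[np.minimum(klass, 2)], alt_map_t[np.maximum(klass - 3, 0)]
    )
    flank5 = rng.integers(0, 4, size=n)
    flank3 = rng.integers(0, 4, size=n)
    # half of the events are recorded on the opposite (purine-centered) strand
    flip = rng.random(n) < 0.5
    comp = np.array([3, 2, 1, 0])
    ref = np.where(flip, comp[ref], ref)
    alt = np.where(flip, comp[alt], alt)
    f5 = np.where(flip, comp[flank3], flank5)
    f3 = np.where(flip, comp[flank5], flank3)
    return ref, alt, f5, f3


class _PatientGenome:
    """Per-patient copy-number segments and (chrom, pos) -> C_t lookup."""

    def __init__(
        self, rng: np.random.Generator, cfg: CohortConfig, purity: float, patient_id: str
    ):
        self.cfg = cfg
        self.purity = purity
        segments: list[CopyNumberSegment] = []
        seg_ct: list[int] = []
        for chrom in cfg.chromosomes:
            k = int(rng.integers(1, cfg.max_segments_per_chromosome + 1))
            if k > 1:
                cuts = np.sort(rng.choice(cfg.chrom_length - 2, size=k - 1, replace=False) + 1)
            else:
                cuts = np.array([], dtype=int)
            bounds = np.concatenate(([0], cuts, [cfg.chrom_length]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                c_t = int(rng.choice([1, 2, 3, 4], p=[0.12, 0.64, 0.14, 0.10]))
                log2 = np.log2((purity * c_t + 2 * (1 - purity)) / 2.0)
                log2 += rng.normal(0.0, 0.03)
                segments.append(
                    CopyNumberSegment(
                        sample_id=patient_id, chrom=chrom, start=int(s), end=int(e),
                        log2_ratio=float(log2),
                    )
                )
                seg_ct.append(c_t)
        self.segments = segments
        self._starts: dict[int, np.ndarray] = {}
        self._cts: dict[int, np.ndarray] = {}
        for ci, chrom in enumerate(cfg.chromosomes):
            idx = [i for i, s in enumerate(segments) if s.chrom == chrom]
            self._starts[ci] = np.array([segments[i].start for i in idx])
            self._cts[ci] = np.array([seg_ct[i] for i in idx])

    def copy_number(self, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.empty(len(pos), dtype=np.int64)
        for ci in np.unique(chrom_idx):
            mask = chrom_idx == ci
            seg_i = np.searchsorted(self._starts[int(ci)], pos[mask], side="right") - 1
            out[mask] = self._cts[int(ci)][seg_i]
        return out


def simulate_cohort(config: CohortConfig, seed: int) -> list[SimulatedSample]:
    """Generate a deterministic, truth-labeled cohort."""
    cfg = config
    root = np.random.SeedSequence(seed)
    pop_seed, roster_seed = root.spawn(2)
    pop_rng = np.random.default_rng(pop_seed)

    # population structure shared by every patient
    n_common = int(cfg.common_snp_per_mb * cfg.exome_mb)
    common = _SitePool(pop_rng, n_common, cfg, indel_prob=0.0)
    common_db_freq = pop_rng.uniform(0.05, 0.5, size=common.n)

    rare = _SitePool(pop_rng, cfg.rare_pool_size, cfg, indel_prob=cfg.indel_fraction[1])
    rare_in_db = pop_rng.random(rare.n) < 0.5
    rare_db_freq = pop_rng.uniform(1e-4, 0.008, size=rare.n)

    anc_pools: dict[str, tuple[_SitePool, np.ndarray, np.ndarray]] = {}
    for gname, group in cfg.ancestry_groups.items():
        pool = _SitePool(pop_rng, cfg.ancestry_pool_size, cfg, indel_prob=cfg.indel_fraction[1])
        in_db = pop_rng.random(pool.n) < group.r_db
        db_freq = pop_rng.uniform(0.01, 0.2, size=pool.n)
        anc_pools[gname] = (pool, in_db, db_freq)

    roster: list[tuple[str, SubtypeSpec]] = []
    for subtype, spec in cfg.subtypes.items():
        roster.extend([(subtype, spec)] * spec.n_patients)
    group_names = list(cfg.ancestry_groups)
    group_fracs = np.array([g.fraction for g in cfg.ancestry_groups.values()])
    roster_rng = np.random.default_rng(roster_seed)
    group_assign = roster_rng.choice(len(group_names), size=len(roster), p=group_fracs)

    child_seeds = root.spawn(len(roster))
    samples: list[SimulatedSample] = []
    for p_idx, ((subtype, spec), seed_seq) in enumerate(zip(roster, child_seeds)):
        rng = np.random.default_rng(seed_seq)
        patient_id = f"P{p_idx:03d}"
        group = group_names[int(group_assign[p_idx])]
        samples.append(
            _simulate_patient(
                rng, cfg, patient_id, subtype, spec, group,
                common, common_db_freq,
                rare, rare_in_db, rare_db_freq,
                anc_pools[group],
            )
        )
    return samples


def _simulate_patient(
    rng, cfg, patient_id, subtype, spec, group,
    common, common_db_freq,
    rare, rare_in_db, rare_db_freq,
    anc_pool,
) -> SimulatedSample:
    purity = float(rng.uniform(*cfg.purity_range))
    genome = _PatientGenome(rng, cfg, purity, patient_id)
    true_tmb = float(rng.uniform(*spec.tmb_range))

    variants: list[VariantCall] = []
    normal_keys: set[tuple] = set()
    somatic_keys: set[tuple] = set()

    # common SNPs: the informative-SNP substrate (non-coding, always in DBs)
    c_idx = np.flatnonzero(rng.random(common.n) < cfg.common_carrier_prob)
    _emit_germline(
        rng, cfg, genome, patient_id, variants, normal_keys,
        common, c_idx,
        hom=rng.random(len(c_idx)) < cfg.hom_fraction,
        db_present=np.ones(len(c_idx), dtype=bool),
        db_freq=common_db_freq[c_idx],
        coding=False,
    )

    # shared rare germline variants (population AF < the prefilter threshold)
    n_rare = int(rng.integers(cfg.rare_germline_range[0], cfg.rare_germline_range[1] + 1))
    r_idx = rng.choice(rare.n, size=min(n_rare, rare.n), replace=False)
    _emit_germline(
        rng, cfg, genome, patient_id, variants, normal_keys,
        rare, r_idx,
        hom=rng.random(len(r_idx)) < 0.05,
        db_present=rare_in_db[r_idx],
        db_freq=rare_db_freq[r_idx],
        coding=True,
    )

    # ancestry-specific germline variants; DB representation depends on r_db
    pool, in_db, db_freq = anc_pool
    n_anc = int(rng.poisson(cfg.ancestry_site_mean))
    a_idx = rng.choice(pool.n, size=min(n_anc, pool.n), replace=False)
    _emit_germline(
        rng, cfg, genome, patient_id, variants, normal_keys,
        pool, a_idx,
        hom=rng.random(len(a_idx)) < 0.1,
        db_present=in_db[a_idx],
        db_freq=db_freq[a_idx],
        coding=True,
    )

    # somatic mutations
    n_som = int(rng.poisson(true_tmb * cfg.exome_mb))
    if n_som > 0:
        total_len = cfg.n_chromosomes * cfg.chrom_length
        flat = rng.integers(0, total_len, size=n_som)
        chrom_idx = flat // cfg.chrom_length
        pos = flat % cfg.chrom_length
        is_indel = rng.random(n_som) < cfg.indel_fraction[0]
        ref_i, alt_i, f5, f3 = _spectrum_alleles(rng, n_som, cfg.spectrum_somatic)
        c_t = genome.copy_number(chrom_idx, pos)
        m = np.ones(n_som, dtype=np.int64)
        multi = (c_t >= 3) & (rng.random(n_som) < 0.25)
        m[multi] = 2
        ccf = np.ones(n_som)
        sub = rng.random(n_som) < cfg.subclonal_fraction
        ccf[sub] = rng.uniform(*cfg.ccf_range, size=int(sub.sum()))
        exp_vaf = np.array(
            [expected_vaf(purity, int(c), int(mm)) for c, mm in zip(c_t, m)]
        ) * ccf
        ontology = rng.choice(5, size=n_som, p=np.asarray(cfg.ontology_somatic))
        cosmic = _draw_cosmic(rng, n_som, cfg.cosmic_p_nonzero[0], cfg.cosmic_geom_p)
        som_db = rng.random(n_som) < 0.01  # occasional coincidental DB entry
        som_db_freq = rng.uniform(1e-4, 0.005, size=n_som)
        _emit_reads(
            rng, cfg, patient_id, variants,
            chrom_idx, pos, ref_i, alt_i, f5, f3, is_indel, exp_vaf,
            ontology, cosmic, som_db, som_db_freq,
            somatic_keys=somatic_keys,
        )

    return SimulatedSample(
        patient_id=patient_id,
        subtype=subtype,
        group=group,
        purity=purity,
        true_tmb_rate=true_tmb,
        variants=variants,
        segments=genome.segments,
        normal_keys=frozenset(normal_keys),
        somatic_keys=frozenset(somatic_keys),
    )


def _emit_germline(
    rng, cfg, genome, patient_id, variants, normal_keys,
    pool, idx, hom, db_present, db_freq, coding,
):
    n = len(idx)
    if n == 0:
        return
    chrom_idx = pool.chrom_idx[idx]
    pos = pool.pos[idx]
    ref_i = pool.ref_idx[idx]
    alt_i = pool.alt_idx[idx]
    f5 = pool.flank5[idx]
    f3 = pool.flank3[idx]
    is_indel = pool.is_indel[idx]
    c_t = genome.copy_number(chrom_idx, pos)
    exp_vaf = np.empty(n)
    for i in range(n):
        if hom[i]:
            exp_vaf[i] = 1.0
        else:
            c = int(c_t[i])
            m = int(rng.integers(1, c)) if c >= 2 else 1
            exp_vaf[i] = expected_vaf(genome.purity, c, m, germline=True)
    if coding:
        ontology = rng.choice(5, size=n, p=np.asarray(cfg.ontology_germline))
    else:
        ontology = np.full(n, 4)  # non-coding -> "other"
    cosmic = _draw_cosmic(rng, n, cfg.cosmic_p_nonzero[1], cfg.cosmic_geom_p)

    # the deep, pure normal sample sees nearly every carried germline site
    detected = rng.random(n) < cfg.normal_detection_prob
    keys = _keys_for(cfg, chrom_idx, pos, ref_i, alt_i, is_indel)
    for i in np.flatnonzero(detected):
        normal_keys.add(keys[i])

    _emit_reads(
        rng, cfg, patient_id, variants,
        chrom_idx, pos, ref_i, alt_i, f5, f3, is_indel, exp_vaf,
        ontology, cosmic, db_present, db_freq,
        somatic_keys=None,
    )


def _keys_for(cfg, chrom_idx, pos, ref_i, alt_i, is_indel):
    keys = []
    for i in range(len(pos)):
        chrom = cfg.chromosomes[int(chrom_idx[i])]
        ref = _BASES[int(ref_i[i])]
        alt = _BASES[int(alt_i[i])]
        if is_indel[i]:
            # deterministic single-base insertion derived from the site alleles
            alt = ref + alt
        keys.append((chrom, int(pos[i]), ref, alt))
    return keys


def _emit_reads(
    rng, cfg, patient_id, variants,
    chrom_idx, pos, ref_i, alt_i, f5, f3, is_indel, exp_vaf,
    ontology, cosmic, db_present, db_freq,
    somatic_keys,
):
    n = len(pos)
    depth = np.maximum(rng.poisson(cfg.mean_depth, size=n), 8)
    alt_reads = rng.binomial(depth, np.clip(exp_vaf, 0.0, 1.0))
    artifact = rng.random(n) < cfg.artifact_fraction
    artifact_kind = rng.random(n) < 0.5
    keys = _keys_for(cfg, chrom_idx, pos, ref_i, alt_i, is_indel)
    is_somatic = somatic_keys is not None
    for i in range(n):
        if alt_reads[i] < cfg.min_alt_reads:
            continue  # below the caller sensitivity floor
        chrom, p, ref, alt = keys[i]
        vaf = alt_reads[i] / depth[i]
        onto = int(ontology[i])
        if is_indel[i]:
            vclass = "insertion" if len(alt) > len(ref) else "deletion"
            tri = NON_SBS
            if onto in (0, 1):  # SNV-only consequences are invalid for indels
                onto = 2
        else:
            vclass = "SNV"
            tri = _BASES[int(f5[i])] + ref + _BASES[int(f3[i])]
            if onto in (2, 3):
                onto = 0
        variants.append(
            VariantCall(
                sample_id=patient_id,
                chrom=chrom,
                pos=p,
                ref=ref,
                alt=alt,
                variant_class=vclass,
                t_alt_freq=float(alt_reads[i] / depth[i]),
                t_maj_allele=float(max(vaf, 1.0 - vaf)),
                depth=int(depth[i]),
                caller_filter="PASS" if not (artifact[i] and artifact_kind[i]) else "t_lod_fstar",
                fpfilter="PASS" if not (artifact[i] and not artifact_kind[i]) else "FAIL",
                ontology=_ONTOLOGY_NAMES[onto],
                db_freqs={"gnomAD_exomes_AF": float(db_freq[i])} if db_present[i] else {},
                cosmic_count=int(cosmic[i]),
                tri_context=tri,
                truth_label=1 if is_somatic else 0,
            )
        )
        if is_somatic:
            somatic_keys.add((chrom, p, ref, alt))


def mvtsm(
    sample: SimulatedSample, kept: Sequence[VariantCall] | None = None
) -> float | None:
    """Median VAF of the true somatic mutations (~ purity/2 in a diploid clonal tumor).

    Computed over the provided kept list when given, otherwise over all
    emitted truth-somatic calls passing both filters. Returns None when the
    sample has no somatic variants.
    """
    if kept is not None:
        vafs = [v.t_alt_freq for v in kept if v.truth_label == 1]
    else:
        vafs = [
            v.t_alt_freq
            for v in sample.variants
            if v.truth_label == 1 and v.caller_filter == "PASS" and v.fpfilter == "PASS"
        ]
    if not vafs:
        return None
    return float(np.median(vafs))


def write_sample(sample: SimulatedSample, directory: str) -> None:
    """Write one sample's tumor VCF, normal sites VCF, SEG, variants TSV, truth JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_variants_vcf(
        sample.variants, str(d / f"{sample.patient_id}.vcf"),
        sample_id=sample.patient_id,
    )
    with open(d / f"{sample.patient_id}.normal.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({k[0] for k in sample.normal_keys}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(sample.normal_keys):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    with open(d / f"{sample.patient_id}.seg", "w") as fh:
        fh.write("chrom\tstart\tend\tlog2\n")
        for s in sample.segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.log2_ratio!r}\n")
    write_variants_tsv(sample.variants, str(d / f"{sample.patient_id}.variants.tsv"))
    truth = {
        "patient_id": sample.patient_id,
        "subtype": sample.subtype,
        "group": sample.group,
        "purity": sample.purity,
        "true_tmb_rate": sample.true_tmb_rate,
        "n_somatic_emitted": sum(v.truth_label == 1 for v in sample.variants),
    }
    (d / f"{sample.patient_id}.truth.json").write_text(json.dumps(truth, indent=2))


def read_sample(directory: str) -> SimulatedSample:
    """Reload a sample written by :func:`write_sample` (from the TSV, not the VCF)."""
    from .variant_io import read_segments, read_variants_tsv

    d = Path(directory)
    truth_path = next(d.glob("*.truth.json"))
    truth = json.loads(truth_path.read_text())
    pid = truth["patient_id"]
    variants = read_variants_tsv(str(d / f"{pid}.variants.tsv"))
    segments = read_segments(str(d / f"{pid}.seg"), sample_id=pid)
    normal_keys = set()
    with open(d / f"{pid}.normal.vcf") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt = line.split("\t")[:5]
            normal_keys.add((chrom, int(pos) - 1, ref, alt))
    somatic_keys = frozenset(v.key for v in variants if v.truth_label == 1)
    return SimulatedSample(
        patient_id=pid,
        subtype=truth["subtype"],
        group=truth["group"],
        purity=truth["purity"],
        true_tmb_rate=truth["true_tmb_rate"],
        variants=variants,
        segments=segments,
        normal_keys=frozenset(normal_keys),
        somatic_keys=somatic_keys,
    )
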