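"""Synthetic multi-setup cohort generator.

The study data this package analyzes — a diploid cohort called independently
under several platform x pipeline "setups" — is not publicly distributable,
so this module synthesizes a self-contained stand-in: a small reference
genome with labelled region tracks (genic partition, repeat families, a GC
gradient, a high-confidence track), population variants with an allele
frequency spectrum that includes rare alleles, per-individual diploid
genotypes drawn in Hardy-Weinberg equilibrium (with a configurable violating
fraction), and per-setup VCF callsets degraded by setup-specific sensitivity,
false-positive rates, genotype errors and representation jitter
(un-left-aligned indels, merged MNPs, multiallelic packing, decoy non-PASS
records).

Region effects are imposed directly through per-(variant class, region
class) profile rates rather than by simulating reads: the artifact tests the
*analysis*, not a variant caller, and desk-scale determinism matters.  All
randomness flows from a single root seed through named substreams (per
individual x setup x stage) so single components can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracks import GenomeIndex, IntervalSet, write_bed
from .variants import (
    Callset,
    ReferenceGenome,
    VariantClass,
    VariantKey,
    VariantRecord,
    classify_variant,
    left_align,
    normalize_callset,
)

logger = logging.getLogger("concordia.simulate")

#: precedence used to assign one region class to a position
REGION_PRECEDENCE = (
    "simple_repeat",
    "low_complexity",
    "alu",
    "line",
    "ltr",
    "exon",
    "intron",
    "intergenic",
)

_BASES = "ACGT"


def _substream(seed: int, *names) -> np.random.Generator:
    """Named, reproducible child stream of the root seed."""
    key = zlib.crc32("/".join(str(n) for n in names).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class JitterConfig:
    """Probabilities for emitting denormalized variant representations."""

    unaligned_indel: float = 0.10
    mnp_merge: float = 0.02
    multiallelic: float = 0.02


@dataclass
class SetupProfile:
    """Error model of one synthetic setup.

    ``sensitivity_overrides`` and ``fp_extra_per_mb`` are keyed by
    ``(variant class name, region class)``; false-positive overrides are
    *additional* rates confined to the named track on top of the genome-wide
    baseline.  ``depth_by_confidence`` holds (mean, dispersion) of a negative
    binomial per high/low confidence stratum.
    """

    label: str
    snp_sensitivity: float = 0.96
    indel_sensitivity: float = 0.80
    sensitivity_overrides: Dict[Tuple[str, str], float] = field(default_factory=dict)
    snp_fp_per_mb: float = 1.5
    indel_fp_per_mb: float = 1.0
    fp_extra_per_mb: Dict[Tuple[str, str], float] = field(default_factory=dict)
    genotype_error: float = 0.002
    jitter: JitterConfig = field(default_factory=JitterConfig)
    depth_by_confidence: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"high": (35.0, 5.0), "low": (18.0, 3.0)}
    )
    decoy_nonpass_fraction: float = 0.02


def default_profiles() -> List[SetupProfile]:
    """The five default setups.

    ``mol-gatk`` and ``hsx-gatk`` share an identical profile (emulating
    harmonized reprocessing of two platforms with the same pipeline);
    ``hsx-isaac`` carries deliberately inflated indel false-positive rates in
    simple-repeat and Alu-like tracks, the qualitative failure mode the
    analysis is meant to recover.
    """
    repeat_penalty = {
        ("SNP", "simple_repeat"): 0.88,
        ("SNP", "low_complexity"): 0.90,
        ("INDEL", "simple_repeat"): 0.60,
        ("INDEL", "low_complexity"): 0.65,
        ("INDEL", "alu"): 0.70,
    }
    gatk = dict(
        snp_sensitivity=0.965,
        indel_sensitivity=0.85,
        sensitivity_overrides=dict(repeat_penalty),
    )
    return [
        SetupProfile(label="cg", snp_sensitivity=0.955, indel_sensitivity=0.72,
                     sensitivity_overrides=dict(repeat_penalty)),
        SetupProfile(label="mol-isaac", snp_sensitivity=0.950, indel_sensitivity=0.78,
                     sensitivity_overrides=dict(repeat_penalty)),
        SetupProfile(
            label="hsx-isaac",
            snp_sensitivity=0.970,
            indel_sensitivity=0.70,
            sensitivity_overrides=dict(repeat_penalty),
            fp_extra_per_mb={
                ("INDEL", "simple_repeat"): 120.0,
                ("INDEL", "alu"): 80.0,
            },
        ),
        SetupProfile(label="mol-gatk", **gatk),
        SetupProfile(label="hsx-gatk", **{**gatk,
                     "sensitivity_overrides": dict(repeat_penalty)}),
    ]


@dataclass
class SimulationConfig:
    """Cohort design: genome layout, variant rates, spectrum, setups."""

    seed: int = 20210119
    n_individuals: int = 99
    contigs: Tuple[Tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    region_layout: Dict[str, float] = field(
        default_factory=lambda: {"exon": 0.03, "intron": 0.40, "intergenic": 0.57}
    )
    repeat_layout: Dict[str, float] = field(
        default_factory=lambda: {
            "alu": 0.08,
            "line": 0.10,
            "ltr": 0.05,
            "low_complexity": 0.01,
            "simple_repeat": 0.03,
        }
    )
    snp_rate_per_kb: float = 0.65
    indel_rate_per_kb: float = 0.13
    rare_fraction: float = 0.35
    rare_af: Tuple[float, float] = (0.005, 0.05)
    common_af: Tuple[float, float] = (0.05, 0.95)
    hwe_violation_fraction: float = 0.02
    hwe_violation_f: float = -0.6  # negative inbreeding coefficient: excess hets
    gc_range: Tuple[float, float] = (0.30, 0.55)
    lowconf_extra_fraction: float = 0.08
    setup_profiles: List[SetupProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        total = sum(self.region_layout.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region_layout fractions must sum to 1, got {total}")
        if self.snp_rate_per_kb < 0 or self.indel_rate_per_kb < 0:
            raise ValueError("variant rates must be >= 0")

    def individuals(self) -> List[str]:
        width = len(str(self.n_individuals))
        return [f"IND{str(i + 1).zfill(width)}" for i in range(self.n_individuals)]


@dataclass
class TruthSet:
    """Reference, tracks, true variants and per-individual genotypes."""

    config: SimulationConfig
    reference: ReferenceGenome
    genome: GenomeIndex
    tracks: Dict[str, IntervalSet]
    sites: Optional[pd.DataFrame] = None  # contig,pos,ref,alt,vclass,region,high_conf,af
    genotypes: Optional[np.ndarray] = None  # (n_sites, n_individuals) dosage 0/1/2

    def individuals(self) -> List[str]:
        return self.config.individuals()

    def site_keys(self) -> List[VariantKey]:
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(
                self.sites["contig"], self.sites["pos"], self.sites["ref"], self.sites["alt"]
            )
        ]

    def true_keys(self, individual: str) -> set:
        i = self.individuals().index(individual)
        carried = np.flatnonzero(self.genotypes[:, i] > 0)
        keys = self.site_keys()
        return {keys[j] for j in carried}


# ---------------------------------------------------------------------------
# reference genome and tracks
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    cum = np.cumsum(p)
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return np.frombuffer(b"ACGT", dtype="S1")[np.clip(idx, 0, 3)]


def _genic_partition(
    rng: np.random.Generator, length: int, layout: Mapping[str, float]
) -> Dict[str, List[Tuple[int, int]]]:
    """Partition [0, length) into exon/intron/intergenic blocks (no gaps)."""
    block_len = {"exon": 200, "intron": 1500, "intergenic": 2500}
    classes = list(layout)
    weights = np.array([layout[c] / block_len[c] for c in classes])
    weights = weights / weights.sum()
    out: Dict[str, List[Tuple[int, int]]] = {c: [] for c in classes}
    pos = 0
    while pos < length:
        cls = classes[rng.choice(len(classes), p=weights)]
        end = min(pos + block_len[cls], length)
        out[cls].append((pos, end))
        pos = end
    return out


_REPEAT_UNIT_LEN = {"alu": 300, "line": 2000, "ltr": 500, "low_complexity": 300}


def _repeat_consensus(rng: np.random.Generator, cls: str) -> np.ndarray:
    if cls == "low_complexity":
        # homopolymer-rich, AT-biased stretch
        parts = []
        total = 0
        while total < _REPEAT_UNIT_LEN[cls]:
            base = rng.choice(list("AATT" "G"))
            run = int(rng.integers(5, 25))
            parts.append(base * run)
            total += run
        seq = "".join(parts)[: _REPEAT_UNIT_LEN[cls]]
        return np.frombuffer(seq.encode(), dtype="S1").copy()
    return _random_seq(rng, _REPEAT_UNIT_LEN[cls], gc=0.42)


def _simple_repeat_unit(rng: np.random.Generator) -> np.ndarray:
    motif = "".join(rng.choice(list(_BASES)) for _ in range(int(rng.integers(2, 7))))
    copies = int(rng.integers(20, 60))
    return np.frombuffer((motif * copies).encode(), dtype="S1").copy()


def build_reference(cfg: SimulationConfig) -> TruthSet:
    """Synthesize contigs with a GC gradient, genic partition and repeats.

    Deterministic given the config seed: the same config yields byte-identical
    FASTA and BED outputs.  The exon/intron/intergenic tracks partition each
    contig exactly; repeat copies are written over the background sequence
    with per-copy divergence and recorded as (possibly overlapping the genic
    partition) tracks; the high-confidence track is the complement of the
    simple-repeat and low-complexity tracks plus extra random low-confidence
    blocks.
    """
    min_len = 4 * max(_REPEAT_UNIT_LEN.values())
    sequences: Dict[str, str] = {}
    genic: Dict[str, list] = {c: [] for c in cfg.region_layout}
    repeat_ivs: Dict[str, list] = {c: [] for c in cfg.repeat_layout}
    lowconf_extra: list = []

    consensus_rng = _substream(cfg.seed, "consensus")
    consensus = {
        cls: _repeat_consensus(consensus_rng, cls)
        for cls in ("alu", "line", "ltr", "low_complexity")
    }

    for contig, length in cfg.contigs:
        if length < min_len:
            raise ValueError(
                f"contig {contig} length {length} below layout minimum {min_len}"
            )
        rng = _substream(cfg.seed, "reference", contig)
        # GC gradient over 100 kb windows so bins span the low/medium/high classes
        window = 100_000
        chunks = []
        n_win = (length + window - 1) // window
        lo, hi = cfg.gc_range
        for w in range(n_win):
            frac = w / max(n_win - 1, 1)
            gc = lo + (hi - lo) * frac
            chunk_len = min(window, length - w * window)
            chunks.append(_random_seq(rng, chunk_len, gc))
        seq = np.concatenate(chunks)

        for cls, blocks in _genic_partition(rng, length, cfg.region_layout).items():
            genic[cls].extend((contig, s, e) for s, e in blocks)

        for cls, fraction in cfg.repeat_layout.items():
            target = int(fraction * length)
            covered = 0
            while covered < target:
                unit = (
                    _simple_repeat_unit(rng)
                    if cls == "simple_repeat"
                    else consensus[cls]
                )
                copy = unit.copy()
                diverge = rng.random(len(copy)) < 0.08
                if diverge.any():
                    copy[diverge] = _random_seq(rng, int(diverge.sum()), gc=0.45)
                start = int(rng.integers(0, length - len(copy)))
                seq[start : start + len(copy)] = copy
                repeat_ivs[cls].append((contig, start, start + len(copy)))
                covered += len(copy)

        n_blocks = max(1, int(cfg.lowconf_extra_fraction * length) // 50_000)
        for _ in range(n_blocks):
            start = int(rng.integers(0, length - 50_000))
            lowconf_extra.append((contig, start, start + 50_000))

        sequences[contig] = seq.tobytes().decode()

    genome: GenomeIndex = {c: l for c, l in cfg.contigs}
    tracks: Dict[str, IntervalSet] = {}
    for cls, ivs in genic.items():
        tracks[cls] = IntervalSet(ivs)
    for cls, ivs in repeat_ivs.items():
        tracks[cls] = IntervalSet(ivs)
    low_conf = tracks["simple_repeat"].union(
        tracks["low_complexity"], IntervalSet(lowconf_extra)
    )
    tracks["giab_high"] = low_conf.complement(genome)

    return TruthSet(
        config=cfg,
        reference=ReferenceGenome(sequences),
        genome=genome,
        tracks=tracks,
    )


# ---------------------------------------------------------------------------
# truth cohort
# ---------------------------------------------------------------------------

def _region_of(tracks: Mapping[str, IntervalSet], contig: str, pos0: int) -> str:
    for cls in REGION_PRECEDENCE:
        if cls in tracks and tracks[cls].contains(contig, pos0):
            return cls
    return "intergenic"


def _sample_af(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    rare = rng.random(n) < cfg.rare_fraction
    af = np.where(
        rare,
        rng.uniform(*cfg.rare_af, size=n),
        rng.uniform(*cfg.common_af, size=n),
    )
    return af


def simulate_truth_cohort(cfg: SimulationConfig, ts: TruthSet) -> TruthSet:
    """Place true variants and draw per-individual diploid genotypes.

    SNP/indel sites are placed uniformly at the configured per-kb rates,
    normalized (left-aligned, deduplicated) and annotated with a region class
    (by precedence) and confidence stratum.  Genotypes are binomial in the
    site's allele frequency (HWE) except for a configured fraction of sites
    drawn with excess heterozygosity (negative inbreeding coefficient).
    Deterministic given the config seed.
    """
    rng = _substream(cfg.seed, "truth")
    genome_bp = sum(l for _, l in cfg.contigs)
    contigs = [c for c, _ in cfg.contigs]
    lengths = np.array([l for _, l in cfg.contigs], dtype=float)
    contig_p = lengths / lengths.sum()

    n_snp = int(round(cfg.snp_rate_per_kb * genome_bp / 1000))
    n_indel = int(round(cfg.indel_rate_per_kb * genome_bp / 1000))

    used: set = set()
    entries: List[Tuple[str, int, str, str]] = []

    def place(vclass: VariantClass) -> None:
        contig = contigs[rng.choice(len(contigs), p=contig_p)]
        length = ts.genome[contig]
        pos = int(rng.integers(2, length - 10))  # 1-based, keep margins
        if (contig, pos) in used:
            return place(vclass)
        used.add((contig, pos))
        anchor = ts.reference.base(contig, pos)
        if vclass is VariantClass.SNP:
            choices = [b for b in _BASES if b != anchor]
            alt = choices[int(rng.integers(0, len(choices)))]
            entries.append((contig, pos, anchor, alt))
            return
        size = int(min(rng.geometric(0.5), 6))
        if rng.random() < 0.5 and pos + size < length:  # deletion
            ref = ts.reference.fetch(contig, pos - 1, pos + size)
            entries.append((contig, pos, ref, anchor))
        else:  # insertion
            ins = "".join(
                _BASES[int(b)] for b in rng.integers(0, 4, size=size)
            )
            entries.append((contig, pos, anchor, anchor + ins))

    for _ in range(n_snp):
        place(VariantClass.SNP)
    for _ in range(n_indel):
        place(VariantClass.INDEL)

    # normalize indel representations against the reference and deduplicate
    norm: Dict[VariantKey, None] = {}
    for contig, pos, ref, alt in entries:
        rec = VariantRecord(contig=contig, pos=pos, ref=ref, alts=[alt])
        if classify_variant(ref, alt) is VariantClass.INDEL:
            rec = left_align(rec, ts.reference)
        key = VariantKey(rec.contig, rec.pos, rec.ref, rec.alt)
        norm.setdefault(key)
    keys = sorted(norm)

    af = _sample_af(rng, cfg, len(keys))
    violates = rng.random(len(keys)) < cfg.hwe_violation_fraction

    n_ind = cfg.n_individuals
    genotypes = rng.binomial(2, af[:, None], size=(len(keys), n_ind)).astype(np.int8)
    f_coeff = cfg.hwe_violation_f
    for j in np.flatnonzero(violates):
        f = af[j]
        p_aa = max(f * f + f_coeff * f * (1 - f), 0.0)
        p_ra = max(2 * f * (1 - f) * (1 - f_coeff), 0.0)
        p_rr = max((1 - f) ** 2 + f_coeff * f * (1 - f), 0.0)
        probs = np.array([p_rr, p_ra, p_aa])
        probs /= probs.sum()
        genotypes[j] = rng.choice(3, size=n_ind, p=probs).astype(np.int8)

    high = ts.tracks["giab_high"]
    sites = pd.DataFrame(
        {
            "contig": [k.contig for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "vclass": [k.variant_class.value for k in keys],
            "region": [
                _region_of(ts.tracks, k.contig, k.pos - 1) for k in keys
            ],
            "high_conf": [high.contains(k.contig, k.pos - 1) for k in keys],
            "af": af,
            "hwe_violating": violates,
        }
    )
    return replace(ts, sites=sites, genotypes=genotypes)


# ---------------------------------------------------------------------------
# per-setup rendering
# ---------------------------------------------------------------------------

def _site_sensitivity(ts: TruthSet, profile: SetupProfile) -> np.ndarray:
    base = {
        "SNP": profile.snp_sensitivity,
        "INDEL": profile.indel_sensitivity,
        "MNP": profile.snp_sensitivity,
    }
    out = np.empty(len(ts.sites), dtype=float)
    for i, (vclass, region) in enumerate(zip(ts.sites["vclass"], ts.sites["region"])):
        out[i] = profile.sensitivity_overrides.get((vclass, region), base[vclass])
    return out


def pad_representation(
    key: VariantKey, reference: ReferenceGenome, times: int = 1
) -> VariantKey:
    """Append shared trailing reference bases: an un-right-trimmed equivalent."""
    contig, pos, ref, alt = key
    for _ in range(times):
        nxt = pos + len(ref)
        if nxt > reference.length(contig):
            break
        pad = reference.base(contig, nxt)
        ref, alt = ref + pad, alt + pad
    return VariantKey(contig, pos, ref, alt)


def right_shift(
    key: VariantKey, reference: ReferenceGenome, times: int = 1
) -> Optional[VariantKey]:
    """Shift an anchored indel one repeat position to the right, if possible."""
    contig, pos, ref, alt = key
    for _ in range(times):
        if len(ref) == len(alt) or not ref or not alt or ref[0] != alt[0]:
            return None
        nxt = pos + len(ref)
        if nxt > reference.length(contig):
            return None
        pad = reference.base(contig, nxt)
        ref, alt, pos = ref[1:] + pad, alt[1:] + pad, pos + 1
    return VariantKey(contig, pos, ref, alt)


def _fp_positions(
    rng: np.random.Generator, iv: IntervalSet, count: int
) -> List[Tuple[str, int]]:
    """Uniform positions (contig, 1-based pos) inside an interval set."""
    spans = list(iv.intervals())
    if not spans or count == 0:
        return []
    widths = np.array([e - s for _, s, e in spans], dtype=float)
    probs = widths / widths.sum()
    picks = rng.choice(len(spans), size=count, p=probs)
    out = []
    for i in picks:
        contig, s, e = spans[i]
        # keep a margin so deletion alleles stay inside the contig
        hi = max(s + 2, e - 8)
        pos0 = int(rng.integers(s + 1, hi)) if hi > s + 1 else s + 1
        out.append((contig, pos0 + 1))
    return out


def _make_fp_record(
    rng: np.random.Generator,
    reference: ReferenceGenome,
    contig: str,
    pos: int,
    vclass: str,
    sample_id: str,
) -> Optional[VariantRecord]:
    anchor = reference.base(contig, pos)
    if anchor == "N":
        return None
    if vclass == "SNP":
        choices = [b for b in _BASES if b != anchor]
        alt = choices[int(rng.integers(0, len(choices)))]
        return VariantRecord(contig=contig, pos=pos, ref=anchor, alts=[alt],
                             genotype=(0, 1), sample_id=sample_id)
    size = int(min(rng.geometric(0.5), 6))
    if rng.random() < 0.5 and pos + size < reference.length(contig):
        ref = reference.fetch(contig, pos - 1, pos + size)
        return VariantRecord(contig=contig, pos=pos, ref=ref, alts=[anchor],
                             genotype=(0, 1), sample_id=sample_id)
    ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=size))
    return VariantRecord(contig=contig, pos=pos, ref=anchor, alts=[anchor + ins],
                         genotype=(0, 1), sample_id=sample_id)


def render_records(
    ts: TruthSet, profile: SetupProfile, individual: str
) -> List[VariantRecord]:
    """Emit one individual's raw callset records under a setup profile.

    True variants carried by the individual are detected with the profile's
    per-(class, region) sensitivity; false positives are added genome-wide at
    the baseline per-Mb rates plus track-confined extra rates; genotypes are
    flipped with the genotype-error probability; representation jitter
    denormalizes a fraction of the emitted records; read depths follow the
    per-confidence-stratum negative binomial; decoy non-PASS records are
    appended.  Deterministic given (config seed, setup label, individual).
    """
    cfg = ts.config
    seed = cfg.seed
    n_sites = len(ts.sites)
    i_ind = ts.individuals().index(individual)
    dosage = ts.genotypes[:, i_ind]

    sens = _site_sensitivity(ts, profile)
    rng_detect = _substream(seed, individual, profile.label, "detect")
    detected = (dosage > 0) & (rng_detect.random(n_sites) < sens)

    rng_gt = _substream(seed, individual, profile.label, "genotype")
    rng_fp = _substream(seed, individual, profile.label, "fp")
    rng_depth = _substream(seed, individual, profile.label, "depth")
    rng_jitter = _substream(seed, individual, profile.label, "jitter")
    rng_decoy = _substream(seed, individual, profile.label, "decoy")

    contigs = ts.sites["contig"].to_numpy()
    positions = ts.sites["pos"].to_numpy()
    refs = ts.sites["ref"].to_numpy()
    alts = ts.sites["alt"].to_numpy()
    high_conf = ts.sites["high_conf"].to_numpy()

    records: List[VariantRecord] = []
    confidences: List[str] = []
    for j in np.flatnonzero(detected):
        gt = (0, 1) if dosage[j] == 1 else (1, 1)
        if rng_gt.random() < profile.genotype_error:
            gt = (1, 1) if gt == (0, 1) else (0, 1)
        records.append(
            VariantRecord(
                contig=str(contigs[j]),
                pos=int(positions[j]),
                ref=str(refs[j]),
                alts=[str(alts[j])],
                genotype=gt,
                sample_id=individual,
            )
        )
        confidences.append("high" if high_conf[j] else "low")

    # false positives: genome-wide baseline + track-confined extras
    genome_mb = sum(ts.genome.values()) / 1e6
    whole = IntervalSet((c, 0, l) for c, l in ts.genome.items())
    fp_plan: List[Tuple[str, IntervalSet, float]] = [
        ("SNP", whole, profile.snp_fp_per_mb * genome_mb),
        ("INDEL", whole, profile.indel_fp_per_mb * genome_mb),
    ]
    for (vclass, region), rate in sorted(profile.fp_extra_per_mb.items()):
        track = ts.tracks.get(region)
        if track is None:
            continue
        fp_plan.append((vclass, track, rate * track.total_length() / 1e6))
    high = ts.tracks["giab_high"]
    for vclass, track, lam in fp_plan:
        count = int(rng_fp.poisson(lam))
        for contig, pos in _fp_positions(rng_fp, track, count):
            rec = _make_fp_record(rng_fp, ts.reference, contig, pos, vclass, individual)
            if rec is not None:
                records.append(rec)
                confidences.append(
                    "high" if high.contains(contig, pos - 1) else "low"
                )

    # read depth per emitted record
    for rec, conf in zip(records, confidences):
        mean, disp = profile.depth_by_confidence[conf]
        p = disp / (disp + mean)
        rec.depth = int(rng_depth.negative_binomial(disp, p)) + 1

    n_emitted = len(records)

    # representation jitter ------------------------------------------------
    jit = profile.jitter
    jittered: List[VariantRecord] = []
    for rec in records:
        if (
            classify_variant(rec.ref, rec.alt) is VariantClass.INDEL
            and rng_jitter.random() < jit.unaligned_indel
        ):
            key = VariantKey(rec.contig, rec.pos, rec.ref, rec.alt)
            moves = int(rng_jitter.integers(1, 3))
            if rng_jitter.random() < 0.5:
                shifted = right_shift(key, ts.reference, times=moves)
                key = shifted if shifted is not None else pad_representation(
                    key, ts.reference, times=moves
                )
            else:
                key = pad_representation(key, ts.reference, times=moves)
            rec = dataclasses.replace(
                rec, pos=key.pos, ref=key.ref, alts=[key.alt]
            )
        jittered.append(rec)
    records = jittered

    # merge adjacent SNP pairs into MNPs
    records.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alts[0]))
    merged: List[VariantRecord] = []
    skip_next = False
    for a, b in zip(records, records[1:] + [None]):
        if skip_next:
            skip_next = False
            continue
        if (
            b is not None
            and a.contig == b.contig
            and b.pos == a.pos + 1
            and len(a.ref) == len(a.alts[0]) == 1
            and len(b.ref) == len(b.alts[0]) == 1
            and rng_jitter.random() < jit.mnp_merge
        ):
            merged.append(
                dataclasses.replace(
                    a, ref=a.ref + b.ref, alts=[a.alts[0] + b.alts[0]]
                )
            )
            skip_next = True
        else:
            merged.append(a)
    records = merged

    # pack a decoy alternate allele onto some SNPs (multiallelic jitter)
    for idx, rec in enumerate(records):
        if (
            len(rec.alts) == 1
            and len(rec.ref) == 1
            and len(rec.alts[0]) == 1
            and rng_jitter.random() < jit.multiallelic
        ):
            decoys = [b for b in _BASES if b not in (rec.ref, rec.alts[0])]
            decoy = decoys[int(rng_jitter.integers(0, len(decoys)))]
            records[idx] = dataclasses.replace(rec, alts=[rec.alts[0], decoy])

    # decoy non-PASS records
    n_decoy = int(rng_decoy.poisson(profile.decoy_nonpass_fraction * n_emitted))
    for contig, pos in _fp_positions(rng_decoy, whole, n_decoy):
        rec = _make_fp_record(rng_decoy, ts.reference, contig, pos, "SNP", individual)
        if rec is not None:
            rec.filter_status = "LowQual"
            rec.depth = 5
            records.append(rec)

    records.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alts[0]))
    return records


def render_normalized(
    ts: TruthSet, profile: SetupProfile, individual: str
) -> Callset:
    """Render one callset and normalize it in memory (no file round-trip)."""
    records = [
        r for r in render_records(ts, profile, individual) if r.filter_status == "PASS"
    ]
    return normalize_callset(
        records, ts.reference, setup_label=profile.label, individual_id=individual
    )


def _write_raw_vcf(
    records: Sequence[VariantRecord],
    path: Path,
    sample: str,
    genome: GenomeIndex,
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=concordia-simulator",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=LowQual,Description="Low quality decoy call">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for contig in sorted(genome):
        lines.append(f"##contig=<ID={contig},length={genome[contig]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for rec in records:
        if rec.genotype is None:
            gt = "./."
        else:
            gt = "/".join("." if a is None else str(a) for a in rec.genotype)
        dp = "." if rec.depth is None else str(rec.depth)
        lines.append(
            f"{rec.contig}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}\t.\t"
            f"{rec.filter_status}\t.\tGT:DP\t{gt}:{dp}"
        )
    path.write_text("\n".join(lines) + "\n")


def render_callset(
    ts: TruthSet, profile: SetupProfile, individual: str, out_path: Path
) -> Path:
    """Render one individual's callset under a profile and write it as VCF."""
    records = render_records(ts, profile, individual)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    _write_raw_vcf(records, out_path, individual, ts.genome)
    return out_path


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _config_to_json(cfg: SimulationConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    return encode(cfg)


def emit_fixture_bundle(
    cfg: SimulationConfig, outdir: Path, force: bool = False
) -> Path:
    """Write a self-contained input bundle for the full analysis pipeline.

    Contents: ``reference.fa`` (+ ``.fai``), one BED per track, one VCF per
    (setup, individual) under ``vcf/<setup>/``, truth tables (sites TSV and
    genotype-dosage TSV), the simulation config as JSON, and a ready-to-run
    pipeline config pointing at the bundle.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    ts = simulate_truth_cohort(cfg, build_reference(cfg))

    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for contig, _ in cfg.contigs:
            fh.write(f">{contig}\n")
            seq = ts.reference.fetch(contig, 0, ts.genome[contig])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    import pyfaidx

    pyfaidx.Fasta(str(fasta))  # create the .fai index alongside

    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    track_paths = {}
    for name, iv in ts.tracks.items():
        track_paths[name] = str(tracks_dir / f"{name}.bed")
        write_bed(iv, track_paths[name])

    vcf_dir = outdir / "vcf"
    for profile in cfg.setup_profiles:
        for individual in ts.individuals():
            render_callset(
                ts, profile, individual, vcf_dir / profile.label / f"{individual}.vcf"
            )

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    ts.sites.to_csv(truth_dir / "sites.tsv", sep="\t", index=False)
    geno = pd.DataFrame(ts.genotypes, columns=ts.individuals())
    geno.insert(0, "pos", ts.sites["pos"].to_numpy())
    geno.insert(0, "contig", ts.sites["contig"].to_numpy())
    geno.to_csv(truth_dir / "genotypes.tsv", sep="\t", index=False)

    (outdir / "simulation_config.json").write_text(
        json.dumps(_config_to_json(cfg), indent=2, sort_keys=True) + "\n"
    )
    pipeline_cfg = {
        "setups": {
            p.label: str(vcf_dir / p.label / "*.vcf") for p in cfg.setup_profiles
        },
        "reference": str(fasta),
        "tracks": track_paths,
        "seed": cfg.seed,
        "output_dir": str(outdir / "results"),
    }
    (outdir / "pipeline_config.json").write_text(
        json.dumps(pipeline_cfg, indent=2, sort_keys=True) + "\n"
    )
    return outdir
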