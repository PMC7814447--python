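"""End-to-end analysis pipeline: from per-setup VCFs to report tables.

Orchestrates the full concordance analysis from a JSON config: callset
normalization, per-individual Venn partitions and Jaccard matrices (overall,
per region track, per GC class), cohort averaging, the Monte-Carlo
enrichment test on the averaged category counts, the GC-content correlation,
and the rare-variant (MAF/HWE) stratification against the high-confidence
track.  All outputs are plain TSV/JSON in the configured output directory.
"""

from __future__ import annotations

import glob
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .concordance import (
    average_over_individuals,
    build_membership,
    concordance_to_frame,
    pairwise_jaccard,
    unique_and_full_counts,
    venn_partition,
    venn_to_frame,
)
from .enrichment import EnrichmentConfig, enrichment_test, result_to_frame, simulate_null
from .tracks import (
    classify_gc_bins,
    compute_gc_bins,
    derive_gc_cutoffs,
    gc_bins_to_frame,
    read_bed,
    restrict_callset,
    spearman_gc_correlation,
    variants_per_bin,
)
from .variants import Callset, ReferenceGenome, VariantClass, normalize_callset, read_vcf

logger = logging.getLogger("concordia.pipeline")

REGION_TRACKS = (
    "exon",
    "intron",
    "intergenic",
    "alu",
    "line",
    "ltr",
    "low_complexity",
    "simple_repeat",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class DataError(ValueError):
    """Input data inconsistent with the configuration (exit code 3)."""


@dataclass
class PipelineConfig:
    setups: Dict[str, str]  # label -> glob of per-individual VCFs
    reference: str
    tracks: Dict[str, str] = field(default_factory=dict)
    giab_track: str = "giab_high"
    gc_bin_size: int = 100_000
    gc_low: float = 0.37
    gc_high: float = 0.47
    gc_derive: bool = False
    maf_threshold: float = 0.05
    hwe_threshold: float = 0.05
    mc_reps: int = 1000
    seed: int = 20210119
    output_dir: str = "concordia_out"
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if len(self.setups) < 2:
            raise ConfigError("need at least 2 setups")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read pipeline config {path}: {exc}") from exc
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class RunReport:
    outputs: Dict[str, str]
    seed: int
    warnings: List[str] = field(default_factory=list)
    counts: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "outputs": self.outputs,
                    "seed": self.seed,
                    "warnings": self.warnings,
                    "counts": self.counts,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _discover_individuals(cfg: PipelineConfig) -> Dict[str, Dict[str, str]]:
    """Map setup -> individual id -> VCF path; ids from file stems."""
    by_setup: Dict[str, Dict[str, str]] = {}
    for label, pattern in cfg.setups.items():
        paths = sorted(glob.glob(pattern))
        if not paths:
            raise DataError(f"setup {label!r}: no files match {pattern!r}")
        by_setup[label] = {}
        for p in paths:
            stem = Path(p).name
            for suffix in (".vcf.gz", ".vcf"):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
                    break
            by_setup[label][stem] = p
    common = set.intersection(*(set(v) for v in by_setup.values()))
    all_ids = set.union(*(set(v) for v in by_setup.values()))
    if common != all_ids and not cfg.allow_missing:
        missing = {
            label: sorted(all_ids - set(v)) for label, v in by_setup.items()
            if all_ids - set(v)
        }
        raise DataError(f"individuals missing in some setups: {missing}")
    return {label: {i: v[i] for i in sorted(common)} for label, v in by_setup.items()}


def load_callsets(cfg: PipelineConfig) -> Dict[str, Dict[str, Callset]]:
    """Read, filter and normalize every (setup, individual) VCF."""
    reference = ReferenceGenome(cfg.reference)
    contigs = set(reference.contigs)
    files = _discover_individuals(cfg)
    callsets: Dict[str, Dict[str, Callset]] = {}
    for label, per_ind in files.items():
        callsets[label] = {}
        for individual, path in per_ind.items():
            records = read_vcf(path, pass_only=True)
            bad = {r.contig for r in records} - contigs
            if bad:
                raise DataError(
                    f"{path}: contigs {sorted(bad)} absent from reference"
                )
            callsets[label][individual] = normalize_callset(
                records, reference, setup_label=label, individual_id=individual
            )
    return callsets


def run_concordance(cfg: PipelineConfig) -> RunReport:
    """Venn partitions and overall Jaccard matrices only (no strata)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outputs={}, seed=cfg.seed)
    callsets = load_callsets(cfg)
    setups = list(cfg.setups)
    individuals = sorted(next(iter(callsets.values())))
    frames = []
    for vclass in (VariantClass.SNP, VariantClass.INDEL):
        rows = [[callsets[label][i] for label in setups] for i in individuals]
        mean_vp = average_over_individuals(
            [venn_partition(build_membership(r, vclass), vclass) for r in rows]
        )
        path = outdir / f"venn_{vclass.value.lower()}.tsv"
        venn_to_frame(mean_vp).to_csv(path, sep="\t", index=False)
        report.outputs[path.name] = str(path)
        mean_cm = average_over_individuals(
            [pairwise_jaccard(r, vclass) for r in rows]
        )
        frames.append(concordance_to_frame(mean_cm))
    path = outdir / "jaccard_overall.tsv"
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    report.outputs[path.name] = str(path)
    return report


def run_rare_variants(cfg: PipelineConfig) -> RunReport:
    """Cohort MAF/HWE filtering, confidence strata and depth summaries only."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outputs={}, seed=cfg.seed)
    reference = ReferenceGenome(cfg.reference)
    genome = reference.genome_index()
    callsets = load_callsets(cfg)
    individuals = sorted(next(iter(callsets.values())))
    giab = (
        read_bed(cfg.tracks[cfg.giab_track]) if cfg.giab_track in cfg.tracks else None
    )
    rare_rows, depth_rows = [], []
    for label in cfg.setups:
        sites = cohort_mod.merge_cohort([callsets[label][i] for i in individuals])
        rv = cohort_mod.rare_hwe_filter(sites, cfg.maf_threshold, cfg.hwe_threshold)
        strata = (
            cohort_mod.confidence_stratify(rv, giab, genome) if giab is not None else {}
        )
        for vclass in (VariantClass.SNP, VariantClass.INDEL):
            rare_rows.append(
                {
                    "setup": label,
                    "variant_class": vclass.value,
                    "n_rare": rv.class_counts().get(vclass, 0),
                    "n_high_conf": strata.get((vclass, "high"), 0),
                    "n_low_conf": strata.get((vclass, "low"), 0),
                }
            )
            for conf in ("high", "low"):
                depth_rows.append(
                    {"setup": label, "variant_class": vclass.value,
                     "confidence": conf,
                     **cohort_mod.depth_distribution(rv, (vclass, conf))}
                )
    for name, rows in (("rare_variants.tsv", rare_rows), ("rare_depth.tsv", depth_rows)):
        path = outdir / name
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        report.outputs[name] = str(path)
    return report


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outputs={}, seed=cfg.seed)

    reference = ReferenceGenome(cfg.reference)
    genome = reference.genome_index()
    callsets = load_callsets(cfg)
    setups = list(cfg.setups)
    individuals = sorted(next(iter(callsets.values())))
    logger.info("loaded %d setups x %d individuals", len(setups), len(individuals))

    tracks = {name: read_bed(path) for name, path in cfg.tracks.items()}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        report.outputs[name] = str(path)

    # GC bins and classes -------------------------------------------------
    bins = compute_gc_bins(reference, genome, bin_size=cfg.gc_bin_size)
    if cfg.gc_derive:
        low_cut, high_cut = derive_gc_cutoffs(bins)
    else:
        low_cut, high_cut = cfg.gc_low, cfg.gc_high
    bins, gc_classes = classify_gc_bins(bins, low_cut, high_cut)
    save("gc_bins.tsv", gc_bins_to_frame(bins))

    jaccard_rows: List[pd.DataFrame] = []
    corr_rows: List[dict] = []
    for vclass in (VariantClass.SNP, VariantClass.INDEL):
        per_ind = [
            [callsets[label][ind] for label in setups] for ind in individuals
        ]

        # Venn partition, cohort average, enrichment ----------------------
        partitions = [
            venn_partition(build_membership(row, vclass), vclass) for row in per_ind
        ]
        mean_vp = average_over_individuals(partitions)
        save(f"venn_{vclass.value.lower()}.tsv", venn_to_frame(mean_vp))

        observed = unique_and_full_counts(mean_vp)
        n_by_setup = {
            label: int(
                round(
                    np.mean(
                        [len(callsets[label][i].keys_of_class(vclass)) for i in individuals]
                    )
                )
            )
            for label in setups
        }
        n_total = int(round(mean_vp.total))
        report.counts[f"{vclass.value}:mean_union"] = mean_vp.total
        if n_total and all(n > 0 for n in n_by_setup.values()):
            mc_cfg = EnrichmentConfig(
                N=n_total, n_by_setup=n_by_setup, reps=cfg.mc_reps, seed=cfg.seed
            )
            null = simulate_null(mc_cfg)
            obs_counts = {
                c: observed[c] for c in mc_cfg.categories()
            }
            result = enrichment_test(obs_counts, null)
            frame = result_to_frame(result)
            frame.insert(0, "variant_class", vclass.value)
            save(f"enrichment_{vclass.value.lower()}.tsv", frame)
            report.counts[f"{vclass.value}:chisq_p"] = result.chisq_p

        # Jaccard: overall, per region track, per GC class -----------------
        strata: Dict[str, Optional[object]] = {"genome": None}
        for name in REGION_TRACKS:
            if name in tracks:
                strata[name] = tracks[name]
        for name, iv in gc_classes.items():
            strata[f"gc_{name}"] = iv
        for stratum, iv in strata.items():
            mats = []
            for row in per_ind:
                restricted = (
                    row if iv is None else [restrict_callset(cs, iv) for cs in row]
                )
                mats.append(pairwise_jaccard(restricted, vclass, stratum=stratum))
            jaccard_rows.append(concordance_to_frame(average_over_individuals(mats)))

        # GC correlation ---------------------------------------------------
        for label in setups:
            per_bin = np.mean(
                [
                    variants_per_bin(callsets[label][i].subset(
                        callsets[label][i].keys_of_class(vclass)
                    ), bins)
                    for i in individuals
                ],
                axis=0,
            )
            rho, p = spearman_gc_correlation(per_bin, bins)
            corr_rows.append(
                {
                    "setup": label,
                    "variant_class": vclass.value,
                    "spearman_rho": rho,
                    "p_value": p,
                }
            )

    save("jaccard.tsv", pd.concat(jaccard_rows, ignore_index=True))
    save("gc_correlation.tsv", pd.DataFrame(corr_rows))

    # rare variants: MAF/HWE filter, confidence strata, depth --------------
    giab = tracks.get(cfg.giab_track)
    rare_rows: List[dict] = []
    depth_rows: List[dict] = []
    cohort_frames: List[pd.DataFrame] = []
    for label in setups:
        sites = cohort_mod.merge_cohort(
            [callsets[label][i] for i in individuals]
        )
        rv = cohort_mod.rare_hwe_filter(
            sites, cfg.maf_threshold, cfg.hwe_threshold
        )
        if giab is not None:
            strata_counts = cohort_mod.confidence_stratify(rv, giab, genome)
        else:
            strata_counts = {}
        for vclass in (VariantClass.SNP, VariantClass.INDEL):
            row = {
                "setup": label,
                "variant_class": vclass.value,
                "n_rare": rv.class_counts().get(vclass, 0),
                "n_high_conf": strata_counts.get((vclass, "high"), 0),
                "n_low_conf": strata_counts.get((vclass, "low"), 0),
            }
            rare_rows.append(row)
            for conf in ("high", "low"):
                summary = cohort_mod.depth_distribution(rv, (vclass, conf))
                depth_rows.append(
                    {"setup": label, "variant_class": vclass.value, "confidence": conf,
                     **summary}
                )
        frame = cohort_mod.cohort_to_frame(sites, rv)
        frame.insert(0, "setup", label)
        cohort_frames.append(frame)

    save("rare_variants.tsv", pd.DataFrame(rare_rows))
    save("rare_depth.tsv", pd.DataFrame(depth_rows))
    save("cohort_sites.tsv", pd.concat(cohort_frames, ignore_index=True))

    report_path = outdir / "run_report.json"
    report.outputs["run_report.json"] = str(report_path)
    report.to_json(report_path)
    return report
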