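"""Synthetic cohort generator: determinism, layout, error-model statistics."""

import dataclasses
import math

import numpy as np
import pytest

from concordia.cohort import hwe_exact_test
from concordia.concordance import build_membership, venn_partition
from concordia.simulate import (
    SimulationConfig,
    build_reference,
    default_profiles,
    emit_fixture_bundle,
    render_normalized,
    render_records,
    simulate_truth_cohort,
)
from concordia.tracks import classify_gc_bins, compute_gc_bins
from concordia.variants import VariantClass
from tests.conftest import SMALL_SIM


def noiseless(profile):
    return dataclasses.replace(
        profile,
        snp_sensitivity=1.0,
        indel_sensitivity=1.0,
        sensitivity_overrides={},
        snp_fp_per_mb=0.0,
        indel_fp_per_mb=0.0,
        fp_extra_per_mb={},
        genotype_error=0.0,
        decoy_nonpass_fraction=0.0,
    )


class TestBuildReference:
    def test_deterministic(self):
        cfg = SimulationConfig(**SMALL_SIM)
        a = build_reference(cfg)
        b = build_reference(cfg)
        for contig, length in cfg.contigs:
            assert a.reference.fetch(contig, 0, length) == b.reference.fetch(
                contig, 0, length
            )
        assert set(a.tracks) == set(b.tracks)
        for name in a.tracks:
            assert a.tracks[name] == b.tracks[name]

    def test_genic_tracks_partition_contigs(self, small_truth):
        genome = small_truth.genome
        total = sum(genome.values())
        covered = sum(
            small_truth.tracks[c].total_length()
            for c in ("exon", "intron", "intergenic")
        )
        assert covered == total
        # pairwise disjoint
        for contig, length in genome.items():
            hits = np.zeros(length // 100, dtype=int)
            probes = np.arange(len(hits)) * 100
            for c in ("exon", "intron", "intergenic"):
                hits += small_truth.tracks[c].contains_many(contig, probes)
            assert np.all(hits == 1)

    def test_gc_gradient_spans_classes(self, small_truth):
        bins = compute_gc_bins(small_truth.reference, bin_size=50_000)
        classified, _ = classify_gc_bins(bins)
        classes = {b.gc_class for b in classified}
        assert {"low", "medium", "high"} <= classes

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            build_reference(SimulationConfig(seed=1, contigs=(("tiny", 1000),)))


class TestTruthCohort:
    def test_rates_control_site_counts(self, small_truth):
        cfg = small_truth.config
        genome_kb = sum(l for _, l in cfg.contigs) / 1000
        n_snp = (small_truth.sites["vclass"] == "SNP").sum()
        n_indel = (small_truth.sites["vclass"] == "INDEL").sum()
        assert n_snp == pytest.approx(cfg.snp_rate_per_kb * genome_kb, rel=0.05)
        assert n_indel == pytest.approx(cfg.indel_rate_per_kb * genome_kb, rel=0.10)

    def test_zero_indel_rate(self):
        cfg = SimulationConfig(**{**SMALL_SIM, "indel_rate_per_kb": 0.0})
        ts = simulate_truth_cohort(cfg, build_reference(cfg))
        assert (ts.sites["vclass"] == "INDEL").sum() == 0

    def test_sites_are_normalized_keys(self, small_truth):
        assert all(k.is_normalized() for k in small_truth.site_keys())

    def test_af_point_mass_recovered_in_genotypes(self):
        cfg = SimulationConfig(
            **{**SMALL_SIM, "n_individuals": 200, "rare_fraction": 1.0,
               "rare_af": (0.02, 0.0200001)}
        )
        ts = simulate_truth_cohort(cfg, build_reference(cfg))
        mean_f = ts.genotypes.mean() / 2
        se = math.sqrt(0.02 * 0.98 / (2 * ts.genotypes.size))
        assert abs(mean_f - 0.02) < 4 * se

    def test_hwe_size_nominal_without_violations(self):
        """In a violation-free cohort the exact test rejects at <= 5%."""
        cfg = SimulationConfig(
            **{**SMALL_SIM, "n_individuals": 80, "hwe_violation_fraction": 0.0,
               "rare_fraction": 0.0, "common_af": (0.1, 0.9)}
        )
        ts = simulate_truth_cohort(cfg, build_reference(cfg))
        pvals = []
        for row in ts.genotypes:
            n_aa = int((row == 2).sum())
            n_ra = int((row == 1).sum())
            n_rr = int((row == 0).sum())
            pvals.append(hwe_exact_test(n_rr, n_ra, n_aa))
        frac = np.mean(np.array(pvals) < 0.05)
        se = math.sqrt(0.05 * 0.95 / len(pvals))
        assert frac <= 0.05 + 3 * se

    def test_violating_sites_show_excess_heterozygosity(self):
        cfg = SimulationConfig(
            **{**SMALL_SIM, "n_individuals": 120, "hwe_violation_fraction": 1.0,
               "rare_fraction": 0.0, "common_af": (0.3, 0.5)}
        )
        ts = simulate_truth_cohort(cfg, build_reference(cfg))
        het = (ts.genotypes == 1).mean(axis=1)
        f = ts.genotypes.mean(axis=1) / 2
        expected_hwe = 2 * f * (1 - f)
        assert het.mean() > expected_hwe.mean() * 1.2


class TestRenderCallset:
    def test_noiseless_render_recovers_truth(self, small_truth):
        profile = noiseless(small_truth.config.setup_profiles[0])
        for ind in ("IND1", "IND3"):
            cs = render_normalized(small_truth, profile, ind)
            assert cs.keys == small_truth.true_keys(ind)

    def test_jitter_does_not_change_key_set(self, small_truth):
        base = noiseless(small_truth.config.setup_profiles[0])
        from concordia.simulate import JitterConfig

        no_jitter = dataclasses.replace(base, jitter=JitterConfig(0.0, 0.0, 0.0))
        heavy_jitter = dataclasses.replace(base, jitter=JitterConfig(0.9, 0.5, 0.5))
        a = render_normalized(small_truth, no_jitter, "IND2")
        b = render_normalized(small_truth, heavy_jitter, "IND2")
        assert a.keys == b.keys

    def test_false_positive_rate_poisson_mean(self, small_truth):
        profile = dataclasses.replace(
            noiseless(small_truth.config.setup_profiles[0]),
            snp_fp_per_mb=50.0,
        )
        genome_mb = sum(small_truth.genome.values()) / 1e6
        lam = 50.0 * genome_mb
        counts = []
        for ind in small_truth.individuals():
            cs = render_normalized(small_truth, profile, ind)
            counts.append(len(cs.keys - small_truth.true_keys(ind)))
        mean = np.mean(counts)
        assert abs(mean - lam) < 3 * math.sqrt(lam / len(counts)) + 2

    def test_determinism_per_individual_setup(self, small_truth):
        profile = small_truth.config.setup_profiles[1]
        a = render_records(small_truth, profile, "IND4")
        b = render_records(small_truth, profile, "IND4")
        assert a == b

    def test_decoy_records_are_non_pass(self, small_truth):
        profile = dataclasses.replace(
            small_truth.config.setup_profiles[0], decoy_nonpass_fraction=0.5
        )
        records = render_records(small_truth, profile, "IND1")
        statuses = {r.filter_status for r in records}
        assert statuses == {"PASS", "LowQual"}


class TestNoiselessCohortAlgebra:
    def test_only_full_intersection_signature(self, small_truth):
        profiles = [noiseless(p) for p in small_truth.config.setup_profiles]
        row = [render_normalized(small_truth, p, "IND5") for p in profiles]
        vp = venn_partition(build_membership(row, VariantClass.SNP))
        full = (1 << len(profiles)) - 1
        assert set(vp.counts) == {full}


class TestFixtureBundle:
    def _tiny_cfg(self, seed=99):
        return SimulationConfig(
            seed=seed,
            n_individuals=2,
            contigs=(("c1", 120_000),),
            setup_profiles=default_profiles()[:2],
        )

    def test_bundle_is_deterministic(self, tmp_path):
        a = emit_fixture_bundle(self._tiny_cfg(), tmp_path / "a")
        b = emit_fixture_bundle(self._tiny_cfg(), tmp_path / "b")
        rel = lambda root: sorted(
            p.relative_to(root) for p in root.rglob("*") if p.is_file()
        )
        assert rel(a) == rel(b)
        for p in rel(a):
            if p.suffix in (".fa", ".bed", ".vcf", ".tsv"):
                assert (a / p).read_bytes() == (b / p).read_bytes(), p

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        out = tmp_path / "bundle"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            emit_fixture_bundle(self._tiny_cfg(), out)
        emit_fixture_bundle(self._tiny_cfg(), out, force=True)

    def test_bundle_contents_complete(self, tmp_path):
        out = emit_fixture_bundle(self._tiny_cfg(), tmp_path / "bundle")
        assert (out / "reference.fa").exists()
        assert (out / "reference.fa.fai").exists()
        assert (out / "pipeline_config.json").exists()
        for name in ("exon", "intron", "intergenic", "simple_repeat", "giab_high"):
            assert (out / "tracks" / f"{name}.bed").exists()
        vcfs = list((out / "vcf").rglob("*.vcf"))
        assert len(vcfs) == 2 * 2  # setups x individuals
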