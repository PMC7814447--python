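"""Shared fixtures: tiny references, VCF writers, and a small synthetic cohort."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from concordia.simulate import SimulationConfig, build_reference, simulate_truth_cohort
from concordia.variants import Callset, ReferenceGenome, VariantKey


@pytest.fixture
def mini_ref() -> ReferenceGenome:
    return ReferenceGenome(
        {
            "chr1": "ACCCCA" + "ATATATG" + "GATTACAGATTACA" + "N" * 3 + "ACGT" * 5,
            "chr2": "ACGTACGTACGTACGTACGT",
        }
    )


@pytest.fixture
def random_ref() -> ReferenceGenome:
    rng = np.random.default_rng(424242)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    return ReferenceGenome({"chrR": seq})


def make_callset(keys, setup="s", individual="i", attrs=None):
    keyset = set(keys)
    return Callset(
        setup_label=setup,
        individual_id=individual,
        keys=keyset,
        attrs=attrs or {k: (30, (0, 1)) for k in keyset},
    )


def snp(pos, contig="chr1", ref="A", alt="G"):
    return VariantKey(contig, pos, ref, alt)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small single-sample VCF from (pos, ref, alt, filter, gt, dp) rows."""

    def _write(rows, name="test.vcf", contig="chr1", contig_len=10_000):
        lines = [
            "##fileformat=VCFv4.2",
            '##FILTER=<ID=PASS,Description="ok">',
            '##FILTER=<ID=q20,Description="low qual">',
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">',
            f"##contig=<ID={contig},length={contig_len}>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
        ]
        for pos, ref, alt, filt, gt, dp in rows:
            lines.append(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT:DP\t{gt}:{dp}"
            )
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


SMALL_SIM = dict(
    seed=1303,
    n_individuals=5,
    contigs=(("c1", 250_000), ("c2", 150_000)),
)


@pytest.fixture(scope="session")
def small_truth():
    cfg = SimulationConfig(**SMALL_SIM)
    return simulate_truth_cohort(cfg, build_reference(cfg))
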