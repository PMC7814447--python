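"""Parsing, classification, normalization and VCF round-trip behaviour."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordia.variants import (
    Callset,
    ReferenceGenome,
    VariantClass,
    VariantKey,
    VariantRecord,
    classify_variant,
    decompose_mnp,
    left_align,
    normalize_callset,
    read_vcf,
    split_multiallelic,
    write_vcf,
)


class TestReadVcf:
    def test_pass_filter_semantics(self, make_vcf):
        path = make_vcf(
            [
                (10, "A", "G", "PASS", "0/1", 20),
                (20, "C", "T", "q20", "0/1", 20),
                (30, "G", "A", "PASS", "1/1", 25),
            ]
        )
        assert len(read_vcf(path, pass_only=True)) == 2
        assert len(read_vcf(path, pass_only=False)) == 3

    def test_dot_filter_is_not_pass(self, make_vcf):
        path = make_vcf([(10, "A", "G", ".", "0/1", 20)])
        skip = Counter()
        assert read_vcf(path, pass_only=True, skip_log=skip) == []
        assert skip["non_pass"] == 1

    def test_symbolic_alt_skipped_and_counted(self, make_vcf):
        path = make_vcf(
            [(10, "A", "<DEL>", "PASS", "0/1", 20), (30, "G", "A", "PASS", "0/1", 9)]
        )
        skip = Counter()
        records = read_vcf(path, pass_only=True, skip_log=skip)
        assert [r.pos for r in records] == [30]
        assert skip["symbolic"] == 1

    def test_depth_and_genotype_come_from_format(self, make_vcf):
        path = make_vcf([(10, "A", "G", "PASS", "0/1", 17)])
        (rec,) = read_vcf(path)
        assert rec.depth == 17
        assert rec.genotype == (0, 1)
        assert rec.sample_id == "S1"

    def test_half_call_genotype_preserved(self, make_vcf):
        path = make_vcf([(10, "A", "G", "PASS", "./1", 8)])
        (rec,) = read_vcf(path)
        assert rec.genotype == (None, 1)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_vcf(tmp_path / "absent.vcf")


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "G", VariantClass.SNP),
        ("AC", "GT", VariantClass.MNP),
        ("AC", "A", VariantClass.INDEL),
        ("A", "ACT", VariantClass.INDEL),
        ("ACGT", "TTTT", VariantClass.MNP),
    ],
)
def test_classify_variant(ref, alt, expected):
    assert classify_variant(ref, alt) is expected


def test_classify_rejects_empty_allele():
    with pytest.raises(ValueError):
        classify_variant("", "A")


class TestSplitMultiallelic:
    def _rec(self, alts, gt):
        return VariantRecord(
            contig="chr1", pos=10, ref="A", alts=alts, genotype=gt, depth=12
        )

    def test_het_alt_pair_recode(self):
        out = split_multiallelic(self._rec(["G", "T"], (1, 2)))
        assert [(r.alt, r.genotype) for r in out] == [("G", (0, 1)), ("T", (0, 1))]
        assert all(r.depth == 12 for r in out)

    def test_biallelic_identity(self):
        out = split_multiallelic(self._rec(["G"], (1, 1)))
        assert [(r.alt, r.genotype) for r in out] == [("G", (1, 1))]

    def test_hom_second_alt_recode(self):
        out = split_multiallelic(self._rec(["G", "T"], (2, 2)))
        assert [(r.alt, r.genotype) for r in out] == [("G", (0, 0)), ("T", (1, 1))]

    @given(
        n_alts=st.integers(1, 3),
        a=st.integers(0, 3),
        b=st.integers(0, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_dosage_conservation(self, n_alts, a, b):
        """Per-alt dosages sum to the record's total non-reference dosage."""
        alts = ["G", "T", "C"][:n_alts]
        gt = (min(a, n_alts), min(b, n_alts))
        out = split_multiallelic(self._rec(alts, gt))
        total = sum(1 for x in gt if x != 0)
        split_total = sum(sum(r.genotype) for r in out)
        assert split_total == total


class TestDecomposeMnp:
    def test_partial_mismatch(self):
        rec = VariantRecord(contig="c", pos=10, ref="ACT", alts=["GCA"])
        out = decompose_mnp(rec)
        assert [(r.pos, r.ref, r.alt) for r in out] == [(10, "A", "G"), (12, "T", "A")]

    def test_full_mismatch(self):
        rec = VariantRecord(contig="c", pos=5, ref="AG", alts=["CT"])
        assert [(r.pos, r.ref, r.alt) for r in decompose_mnp(rec)] == [
            (5, "A", "C"),
            (6, "G", "T"),
        ]

    def test_identity_mnp_rejected(self):
        rec = VariantRecord(contig="c", pos=5, ref="AG", alts=["AG"])
        with pytest.raises(ValueError):
            decompose_mnp(rec)

    def test_non_mnp_rejected(self):
        rec = VariantRecord(contig="c", pos=5, ref="A", alts=["G"])
        with pytest.raises(ValueError):
            decompose_mnp(rec)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_output_count_is_hamming_distance(self, data):
        n = data.draw(st.integers(2, 8))
        bases = st.sampled_from("ACGT")
        ref = "".join(data.draw(st.lists(bases, min_size=n, max_size=n)))
        alt = "".join(data.draw(st.lists(bases, min_size=n, max_size=n)))
        if ref == alt:
            return
        rec = VariantRecord(contig="c", pos=100, ref=ref, alts=[alt])
        hamming = sum(1 for r, a in zip(ref, alt) if r != a)
        assert len(decompose_mnp(rec)) == hamming


class TestLeftAlign:
    def test_deletion_in_homopolymer(self):
        ref = ReferenceGenome({"c": "ACCCCA"})
        rec = VariantRecord(contig="c", pos=2, ref="CC", alts=["C"])
        out = left_align(rec, ref)
        assert (out.pos, out.ref, out.alt) == (1, "AC", "A")

    def test_snp_unchanged(self, mini_ref):
        rec = VariantRecord(contig="chr1", pos=3, ref="C", alts=["T"])
        out = left_align(rec, mini_ref)
        assert (out.pos, out.ref, out.alt) == (3, "C", "T")

    def test_dinucleotide_repeat_deletion(self):
        ref = ReferenceGenome({"c": "ATATATG"})
        rec = VariantRecord(contig="c", pos=3, ref="ATA", alts=["A"])
        out = left_align(rec, ref)
        assert (out.pos, out.ref, out.alt) == (1, "ATA", "A")

    def test_reference_mismatch_passes_through(self, caplog):
        ref = ReferenceGenome({"c": "AAAAAA"})
        rec = VariantRecord(contig="c", pos=2, ref="CC", alts=["C"])
        out = left_align(rec, ref)
        assert (out.pos, out.ref, out.alt) == (2, "CC", "C")

    def test_output_is_normalized_key(self, random_ref):
        """Randomly padded/shifted indels all map to parsimonious keys."""
        from concordia.simulate import pad_representation, right_shift

        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(200):
            pos = int(rng.integers(10, 9_000))
            anchor = random_ref.base("chrR", pos)
            if rng.random() < 0.5:
                ref_allele = random_ref.fetch("chrR", pos - 1, pos + int(rng.integers(1, 5)))
                key = VariantKey("chrR", pos, ref_allele, anchor)
            else:
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 5))))
                key = VariantKey("chrR", pos, anchor, anchor + ins)
            variants = [pad_representation(key, random_ref, times=2)]
            shifted = right_shift(key, random_ref)
            if shifted is not None:
                variants.append(shifted)
            for v in variants:
                rec = VariantRecord(contig=v.contig, pos=v.pos, ref=v.ref, alts=[v.alt])
                out = left_align(rec, random_ref)
                got = VariantKey(out.contig, out.pos, out.ref, out.alt)
                assert got.is_normalized()


class TestNormalizeCallset:
    def test_equivalent_representations_collapse(self):
        ref = ReferenceGenome({"c": "ACCCCCA"})
        # the same single-C deletion written at two right-shifted positions
        recs = [
            VariantRecord(contig="c", pos=2, ref="CC", alts=["C"], genotype=(0, 1)),
            VariantRecord(contig="c", pos=4, ref="CC", alts=["C"], genotype=(0, 1)),
        ]
        cs = normalize_callset(recs, ref, "s", "i")
        assert cs.keys == {VariantKey("c", 1, "AC", "A")}

    def test_empty_input(self, mini_ref):
        cs = normalize_callset([], mini_ref, "s", "i")
        assert len(cs) == 0

    def test_mnp_becomes_two_snps(self, mini_ref):
        rec = VariantRecord(contig="chr1", pos=7, ref="AT", alts=["CG"], genotype=(0, 1))
        cs = normalize_callset([rec], mini_ref, "s", "i")
        assert cs.keys == {
            VariantKey("chr1", 7, "A", "C"),
            VariantKey("chr1", 8, "T", "G"),
        }

    def test_zero_dosage_alt_dropped(self, mini_ref):
        rec = VariantRecord(
            contig="chr1", pos=3, ref="C", alts=["G", "T"], genotype=(2, 2)
        )
        cs = normalize_callset([rec], mini_ref, "s", "i")
        assert cs.keys == {VariantKey("chr1", 3, "C", "T")}

    def test_duplicate_keys_keep_max_depth(self, mini_ref):
        recs = [
            VariantRecord(contig="chr1", pos=3, ref="C", alts=["T"], depth=9, genotype=(0, 1)),
            VariantRecord(contig="chr1", pos=3, ref="C", alts=["T"], depth=31, genotype=(1, 1)),
        ]
        cs = normalize_callset(recs, mini_ref, "s", "i")
        key = VariantKey("chr1", 3, "C", "T")
        assert cs.attrs[key][0] == 31


class TestWriteVcf:
    def test_round_trip_identity(self, tmp_path, random_ref):
        keys = {
            VariantKey("chrR", 100, random_ref.base("chrR", 100), "T"
                       if random_ref.base("chrR", 100) != "T" else "G"),
            VariantKey("chrR", 200, random_ref.base("chrR", 200),
                       random_ref.base("chrR", 200) + "ACG"),
        }
        cs = Callset(setup_label="s", individual_id="i", keys=keys,
                     attrs={k: (15, (0, 1)) for k in keys})
        path = write_vcf(cs, tmp_path / "out.vcf", genome_index=random_ref.genome_index())
        back = normalize_callset(read_vcf(path), random_ref, "s", "i")
        assert back.keys == cs.keys
        assert all(back.attrs[k] == (15, (0, 1)) for k in keys)

    def test_empty_callset_header_only(self, tmp_path):
        cs = Callset(setup_label="s", individual_id="i")
        path = write_vcf(cs, tmp_path / "empty.vcf")
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    def test_sorted_by_contig_then_position(self, tmp_path):
        keys = [
            VariantKey("chr2", 5, "A", "G"),
            VariantKey("chr1", 50, "A", "G"),
            VariantKey("chr1", 5, "A", "G"),
        ]
        cs = Callset(setup_label="s", individual_id="i", keys=set(keys),
                     attrs={k: (1, (0, 1)) for k in keys})
        path = write_vcf(cs, tmp_path / "sorted.vcf")
        data = [l.split("\t")[:2] for l in path.read_text().splitlines()
                if not l.startswith("#")]
        assert data == [["chr1", "5"], ["chr1", "50"], ["chr2", "5"]]


def test_normalization_idempotent_on_rendered_cohort(tmp_path, small_truth):
    """write(normalize(X)) re-read and re-normalized is a fixed point."""
    cfg = small_truth.config
    from concordia.simulate import render_normalized

    cs = render_normalized(small_truth, cfg.setup_profiles[0], "IND1")
    path = write_vcf(cs, tmp_path / "norm.vcf",
                     genome_index=small_truth.genome)
    again = normalize_callset(
        read_vcf(path), small_truth.reference, cs.setup_label, cs.individual_id
    )
    assert again.keys == cs.keys
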