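"""Variant callset parsing, normalization and canonical identity.

Variant calls produced by heterogeneous sequencing platforms and calling
pipelines encode the same underlying allele in different ways: multiallelic
records, multi-nucleotide substitutions (MNPs) instead of runs of SNPs, and
indels placed at any of their equivalent positions inside a repeat.  Before
callsets can be intersected, every call has to be reduced to a canonical
biallelic key ``(contig, pos, ref, alt)`` that is left-aligned against the
reference and stripped of redundant flanking bases.  This module provides the
record model, the normalization pipeline, and VCF input/output for those
normalized callsets.

Variant identity here is allele-aware but genotype-agnostic: two callsets
agree on a variant if they call the same alternate allele at the same
normalized position, regardless of zygosity.  Genotypes and read depths are
carried along as per-key attributes for downstream cohort statistics.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Tuple, Union

import pyfaidx
import pysam

logger = logging.getLogger("concordia.variants")

_DNA_RE = re.compile(r"^[ACGTN]+$")

#: genotype: pair of allele indices; ``None`` entries are uncalled alleles,
#: a ``None`` value means the whole genotype is missing.
Genotype = Optional[Tuple[Optional[int], ...]]


class VcfParseError(ValueError):
    """A VCF file or record could not be parsed."""


class NormalizationError(ValueError):
    """A record could not be normalized against the reference."""


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    MNP = "MNP"
    OTHER = "OTHER"


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a biallelic ``ref -> alt`` change by allele lengths.

    Equal length one: SNP; equal length >1: MNP; unequal lengths: INDEL.
    """
    if not ref or not alt:
        raise ValueError("ref and alt alleles must be non-empty")
    if len(ref) == len(alt):
        return VariantClass.SNP if len(ref) == 1 else VariantClass.MNP
    return VariantClass.INDEL


class VariantKey(NamedTuple):
    """Canonical identity of a normalized biallelic variant (1-based pos)."""

    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def variant_class(self) -> VariantClass:
        return classify_variant(self.ref, self.alt)

    def is_normalized(self) -> bool:
        """Parsimony check: no trimmable shared flanking base remains."""
        r, a = self.ref, self.alt
        right_ok = len(r) == 1 or len(a) == 1 or r[-1] != a[-1]
        left_ok = len(r) == 1 or len(a) == 1 or r[0] != a[0]
        return right_ok and left_ok


@dataclass(slots=True)
class VariantRecord:
    """One (possibly multiallelic) variant call for one sample."""

    contig: str
    pos: int
    ref: str
    alts: list
    filter_status: str = "PASS"
    depth: Optional[int] = None
    genotype: Genotype = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.ref = self.ref.upper()
        self.alts = [a.upper() for a in self.alts]
        for allele in (self.ref, *self.alts):
            if not _DNA_RE.match(allele):
                raise ValueError(f"allele {allele!r} is not a plain DNA string")

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError("record is not biallelic")
        return self.alts[0]


@dataclass
class Callset:
    """Normalized variant keys called for one individual under one setup."""

    setup_label: str
    individual_id: str
    genome_build: str = "synthetic"
    keys: set = field(default_factory=set)
    attrs: dict = field(default_factory=dict)  # VariantKey -> (depth, genotype)

    def __len__(self) -> int:
        return len(self.keys)

    def keys_of_class(self, variant_class: VariantClass) -> set:
        return {k for k in self.keys if k.variant_class is variant_class}

    def subset(self, keys: Iterable[VariantKey]) -> "Callset":
        keep = set(keys) & self.keys
        return Callset(
            setup_label=self.setup_label,
            individual_id=self.individual_id,
            genome_build=self.genome_build,
            keys=keep,
            attrs={k: self.attrs[k] for k in keep if k in self.attrs},
        )


class ReferenceGenome:
    """Sequence accessor over an indexed FASTA file or an in-memory mapping.

    ``fetch`` uses 0-based half-open coordinates; ``base`` takes a 1-based
    position (VCF convention).  Sequences are reported uppercased.
    """

    def __init__(self, source: Union[str, Path, Mapping[str, str]]):
        if isinstance(source, (str, Path)):
            self._fasta = pyfaidx.Fasta(str(source), sequence_always_upper=True)
            self._mem = None
        else:
            self._fasta = None
            self._mem = {name: str(seq).upper() for name, seq in source.items()}

    @property
    def contigs(self) -> list:
        if self._mem is not None:
            return list(self._mem)
        return list(self._fasta.keys())

    def length(self, contig: str) -> int:
        if self._mem is not None:
            return len(self._mem[contig])
        return len(self._fasta[contig])

    def genome_index(self) -> dict:
        return {c: self.length(c) for c in self.contigs}

    def fetch(self, contig: str, start0: int, end0: int) -> str:
        if start0 < 0 or end0 > self.length(contig):
            raise NormalizationError(
                f"fetch [{start0}, {end0}) outside contig {contig!r}"
            )
        if self._mem is not None:
            return self._mem[contig][start0:end0]
        return str(self._fasta[contig][start0:end0])

    def base(self, contig: str, pos1: int) -> str:
        return self.fetch(contig, pos1 - 1, pos1)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*")


def read_vcf(
    path: Union[str, Path],
    pass_only: bool = True,
    skip_log: Optional[Counter] = None,
) -> list:
    """Read a VCF 4.x file (plain or bgzipped) into :class:`VariantRecord`.

    One record is emitted per data line per sample; for sites without sample
    columns a single record with a missing genotype is emitted.  Depth is read
    from ``FORMAT/DP`` falling back to ``INFO/DP``.  With ``pass_only`` only
    lines whose FILTER is exactly ``PASS`` are returned; a bare ``.`` FILTER is
    *not* treated as PASS.  Symbolic/breakend alleles are skipped and counted
    in *skip_log* (keys ``symbolic``, ``non_pass``, ``bad_allele``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    skip = skip_log if skip_log is not None else Counter()
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - malformed header
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    records: list = []
    with vf:
        samples = list(vf.header.samples)
        info_has_dp = "DP" in vf.header.info
        format_has_dp = "DP" in vf.header.formats
        for line_idx, rec in enumerate(vf, start=1):
            try:
                alts = rec.alts or ()
                if not alts:
                    skip["no_alt"] += 1
                    continue
                if any(_is_symbolic(a) for a in alts):
                    skip["symbolic"] += 1
                    continue
                filters = list(rec.filter.keys())
                status = ";".join(filters) if filters else "."
                if pass_only and status != "PASS":
                    skip["non_pass"] += 1
                    continue
                if not _DNA_RE.match(rec.ref.upper()) or any(
                    not _DNA_RE.match(a.upper()) for a in alts
                ):
                    skip["bad_allele"] += 1
                    continue
                info_dp = rec.info.get("DP") if info_has_dp else None
                if isinstance(info_dp, tuple):
                    info_dp = info_dp[0]
                if samples:
                    for sid in samples:
                        sample = rec.samples[sid]
                        gt = sample.get("GT")
                        if gt is not None and all(a is None for a in gt):
                            gt = None
                        dp = sample.get("DP") if format_has_dp else None
                        if dp is None:
                            dp = info_dp
                        records.append(
                            VariantRecord(
                                contig=rec.contig,
                                pos=rec.pos,
                                ref=rec.ref,
                                alts=list(alts),
                                filter_status=status,
                                depth=int(dp) if dp is not None else None,
                                genotype=tuple(gt) if gt is not None else None,
                                sample_id=sid,
                            )
                        )
                else:
                    records.append(
                        VariantRecord(
                            contig=rec.contig,
                            pos=rec.pos,
                            ref=rec.ref,
                            alts=list(alts),
                            filter_status=status,
                            depth=int(info_dp) if info_dp is not None else None,
                            genotype=None,
                            sample_id="",
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise VcfParseError(
                    f"{path}: malformed VCF data record #{line_idx}: {exc}"
                ) from exc
    if skip:
        logger.info("read_vcf(%s): skipped %s", path.name, dict(skip))
    return records


def _format_gt(genotype: Genotype) -> str:
    if genotype is None:
        return "./."
    return "/".join("." if a is None else str(a) for a in genotype)


def write_vcf(
    cs: Callset,
    path: Union[str, Path],
    genome_index: Optional[Mapping[str, int]] = None,
) -> Path:
    """Write a normalized callset as a minimal sorted VCF 4.2 file.

    All records carry FILTER ``PASS`` and ``GT:DP`` for the single sample.
    Round-trips through :func:`read_vcf` + :func:`normalize_callset` to an
    identical key set.
    """
    path = Path(path)
    ordered = sorted(cs.keys)
    lengths: dict = dict(genome_index) if genome_index else {}
    for key in ordered:
        need = key.pos + len(key.ref)
        lengths[key.contig] = max(lengths.get(key.contig, 0), need)
    sample = cs.individual_id or "SAMPLE"
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=concordia ({cs.setup_label})",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for contig in sorted(lengths):
        lines.append(f"##contig=<ID={contig},length={lengths[contig]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for key in ordered:
        depth, genotype = cs.attrs.get(key, (None, None))
        dp = "." if depth is None else str(int(depth))
        lines.append(
            f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\t"
            f"GT:DP\t{_format_gt(genotype)}:{dp}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Normalization pipeline
# ---------------------------------------------------------------------------

def split_multiallelic(rec: VariantRecord) -> list:
    """Split a record into one biallelic record per alternate allele.

    The genotype of each output record is recoded as presence/absence of that
    alt: dosage 0 -> ``(0, 0)``, 1 -> ``(0, 1)``, 2 -> ``(1, 1)``.  Half-calls
    such as ``./1`` therefore carry the alt with dosage one.  Depth is copied
    unchanged.
    """
    if not rec.alts:
        raise ValueError("record has no alternate alleles")
    out = []
    for j, alt in enumerate(rec.alts, start=1):
        if rec.genotype is None:
            gt: Genotype = None
        else:
            dosage = sum(1 for a in rec.genotype if a == j)
            gt = {0: (0, 0), 1: (0, 1)}.get(dosage, (1, 1))
        out.append(
            VariantRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alts=[alt],
                filter_status=rec.filter_status,
                depth=rec.depth,
                genotype=gt,
                sample_id=rec.sample_id,
            )
        )
    return out


def decompose_mnp(rec: VariantRecord) -> list:
    """Decompose a biallelic MNP into its constituent SNPs.

    Every offset where ref and alt disagree yields one SNP; matching offsets
    are dropped.  Genotype and depth are copied to each SNP.
    """
    ref, alt = rec.ref, rec.alt
    if ref == alt:
        raise ValueError("ref == alt: not a variant")
    if classify_variant(ref, alt) is not VariantClass.MNP:
        raise ValueError(f"decompose_mnp called on non-MNP {ref}->{alt}")
    out = []
    for i, (r, a) in enumerate(zip(ref, alt)):
        if r != a:
            out.append(
                VariantRecord(
                    contig=rec.contig,
                    pos=rec.pos + i,
                    ref=r,
                    alts=[a],
                    filter_status=rec.filter_status,
                    depth=rec.depth,
                    genotype=rec.genotype,
                    sample_id=rec.sample_id,
                )
            )
    return out


def left_align(rec: VariantRecord, reference: ReferenceGenome) -> VariantRecord:
    """Left-normalize a biallelic record against the reference.

    Shared trailing bases are trimmed (extending to the left through the
    reference when an allele would become empty), then shared leading bases
    are trimmed.  SNPs are returned unchanged.  If the record's ref allele
    does not match the reference sequence the record is passed through with a
    warning rather than aborting the cohort.
    """
    ref, alt, pos = rec.ref, rec.alt, rec.pos
    if len(ref) == 1 and len(alt) == 1:
        return rec
    expected = reference.fetch(rec.contig, pos - 1, pos - 1 + len(ref))
    if expected != ref:
        logger.warning(
            "left_align: ref allele %s at %s:%d does not match reference %s; "
            "record passed through unchanged",
            ref,
            rec.contig,
            pos,
            expected,
        )
        return rec
    while len(ref) > 1 or len(alt) > 1:
        if ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break  # cannot extend past the contig start
                pad = reference.base(rec.contig, pos - 1)
                ref, alt, pos = pad + ref, pad + alt, pos - 1
            ref, alt = ref[:-1], alt[:-1]
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        else:
            break
    return replace(rec, pos=pos, ref=ref, alts=[alt])


def normalize_callset(
    records: Iterable[VariantRecord],
    reference: ReferenceGenome,
    setup_label: str,
    individual_id: str,
    genome_build: str = "synthetic",
) -> Callset:
    """Reduce raw records to a canonical, deduplicated key set.

    Pipeline: split multiallelics -> decompose MNPs -> left-align indels ->
    drop per-alt genotypes of ``0/0`` and degenerate ``ref == alt`` records ->
    deduplicate by key keeping the maximum depth.  The operation is
    idempotent: normalizing a written-out normalized callset is a no-op.
    """
    best: dict = {}
    for rec in records:
        for bi in split_multiallelic(rec):
            if bi.genotype == (0, 0):
                continue
            if bi.ref == bi.alt:
                continue
            vclass = classify_variant(bi.ref, bi.alt)
            if vclass is VariantClass.MNP:
                pieces = decompose_mnp(bi)
            elif vclass is VariantClass.INDEL:
                pieces = [left_align(bi, reference)]
            else:
                pieces = [bi]
            for piece in pieces:
                if piece.ref == piece.alt:
                    continue
                key = VariantKey(piece.contig, piece.pos, piece.ref, piece.alt)
                prev = best.get(key)
                if prev is None:
                    best[key] = (piece.depth, piece.genotype)
                else:
                    prev_depth = prev[0] if prev[0] is not None else -1
                    depth = piece.depth if piece.depth is not None else -1
                    if depth > prev_depth:
                        best[key] = (piece.depth, piece.genotype)
    return Callset(
        setup_label=setup_label,
        individual_id=individual_id,
        genome_build=genome_build,
        keys=set(best),
        attrs=best,
    )
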