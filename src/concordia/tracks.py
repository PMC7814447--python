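"""Genomic interval tracks, region stratification and GC-content binning.

Annotation tracks (exon/intron/intergenic, RepeatMasker classes, GIAB-style
high-confidence intervals) are consumed as BED3 files with 0-based half-open
coordinates and held as merged, sorted interval arrays per contig.  Variant
membership is tested on the variant's anchor base only (VCF ``pos`` converted
to 0-based), so an indel spanning a region boundary is assigned by its anchor.

GC content is computed over fixed-size bins (default 100 kbp) as the
proportion of G/C among unambiguous bases; bins are classified as low /
medium / high GC with configurable cutoffs (defaults 37% / 47%), and variant
density per bin supports a Spearman rank correlation against GC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .variants import Callset, ReferenceGenome

logger = logging.getLogger("concordia.tracks")

#: map contig -> length in bases
GenomeIndex = Dict[str, int]


class BedParseError(ValueError):
    pass


class IntervalSet:
    """Per-contig sorted, merged, half-open 0-based intervals."""

    __slots__ = ("_ivs",)

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = ()):
        by_contig: Dict[str, list] = {}
        for contig, start, end in intervals:
            if start < 0 or start >= end:
                raise ValueError(f"bad interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((int(start), int(end)))
        self._ivs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for contig, pairs in by_contig.items():
            pairs.sort()
            merged: list = []
            for start, end in pairs:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._ivs[contig] = (starts, ends)

    # -- basic introspection ------------------------------------------------
    @property
    def contigs(self) -> List[str]:
        return sorted(self._ivs)

    def intervals(self) -> Iterable[Tuple[str, int, int]]:
        for contig in self.contigs:
            starts, ends = self._ivs[contig]
            for s, e in zip(starts, ends):
                yield contig, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._ivs.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self.intervals()) == list(other.intervals())

    def total_length(self, contig: Optional[str] = None) -> int:
        contigs = [contig] if contig else self.contigs
        total = 0
        for c in contigs:
            if c in self._ivs:
                starts, ends = self._ivs[c]
                total += int((ends - starts).sum())
        return total

    # -- membership ---------------------------------------------------------
    def contains(self, contig: str, pos0: int) -> bool:
        return bool(self.contains_many(contig, np.array([pos0]))[0])

    def contains_many(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 0-based positions."""
        if contig not in self._ivs:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = self._ivs[contig]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        result = np.zeros(len(positions), dtype=bool)
        result[ok] = positions[ok] < ends[idx[ok]]
        return result

    # -- set algebra ---------------------------------------------------------
    def union(self, *others: "IntervalSet") -> "IntervalSet":
        items = list(self.intervals())
        for other in others:
            items.extend(other.intervals())
        return IntervalSet(items)

    def complement(self, genome: GenomeIndex) -> "IntervalSet":
        """Set complement per contig over ``[0, length)``."""
        out = []
        for contig, length in genome.items():
            cursor = 0
            if contig in self._ivs:
                starts, ends = self._ivs[contig]
                if len(ends) and ends[-1] > length:
                    raise ValueError(
                        f"interval beyond contig {contig} length {length}"
                    )
                for s, e in zip(starts, ends):
                    if s > cursor:
                        out.append((contig, cursor, int(s)))
                    cursor = int(e)
            if cursor < length:
                out.append((contig, cursor, length))
        return IntervalSet(out)


def read_bed(path: Union[str, Path]) -> IntervalSet:
    """Read a BED3+ file (columns beyond 3 ignored) into a merged IntervalSet."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{line_no}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{line_no}: invalid interval [{start}, {end})"
                )
            intervals.append((fields[0], start, end))
    return IntervalSet(intervals)


def write_bed(iv: IntervalSet, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for contig, start, end in iv.intervals():
            fh.write(f"{contig}\t{start}\t{end}\n")
    return path


def complement_intervals(iv: IntervalSet, genome: GenomeIndex) -> IntervalSet:
    """Set complement of a track per contig over ``[0, length)``."""
    return iv.complement(genome)


def restrict_callset(cs: Callset, iv: IntervalSet) -> Callset:
    """Keep keys whose anchor base (``pos - 1``, 0-based) lies in the track."""
    by_contig: Dict[str, list] = {}
    for key in cs.keys:
        by_contig.setdefault(key.contig, []).append(key)
    keep = []
    for contig, keys in by_contig.items():
        positions = np.array([k.pos - 1 for k in keys], dtype=np.int64)
        mask = iv.contains_many(contig, positions)
        keep.extend(k for k, m in zip(keys, mask) if m)
    return cs.subset(keep)


# ---------------------------------------------------------------------------
# GC binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCBin:
    contig: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: Optional[float] = None
    gc_class: Optional[str] = None


def compute_gc_bins(
    reference: ReferenceGenome,
    genome: Optional[GenomeIndex] = None,
    bin_size: int = 100_000,
) -> List[GCBin]:
    """Tile every contig with fixed-size bins and compute GC per bin.

    ``gc_fraction = (#G + #C) / (#A + #C + #G + #T)``; N and other ambiguity
    codes count in neither numerator nor denominator.  A bin with no
    unambiguous base gets a missing fraction.  The last bin per contig may be
    short.
    """
    if genome is None:
        genome = reference.genome_index()
    bins: List[GCBin] = []
    for contig, length in genome.items():
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            seq = reference.fetch(contig, start, end).upper()
            gc = seq.count("G") + seq.count("C")
            at = seq.count("A") + seq.count("T")
            denom = gc + at
            frac = gc / denom if denom else None
            bins.append(GCBin(contig=contig, start=start, end=end, gc_fraction=frac))
    return bins


def gc_quantile_report(bins: Sequence[GCBin]) -> Dict[str, float]:
    """Empirical quantiles (6th, 30th, median, 90th, 95th, max) of bin GC."""
    values = np.array([b.gc_fraction for b in bins if b.gc_fraction is not None])
    if len(values) == 0:
        raise ValueError("no bins with a defined GC fraction")
    return {
        "p06": float(np.quantile(values, 0.06)),
        "p30": float(np.quantile(values, 0.30)),
        "median": float(np.quantile(values, 0.50)),
        "p90": float(np.quantile(values, 0.90)),
        "p95": float(np.quantile(values, 0.95)),
        "max": float(values.max()),
    }


def derive_gc_cutoffs(bins: Sequence[GCBin]) -> Tuple[float, float]:
    """Derive low/high GC cutoffs from the bin distribution.

    The low cutoff is the 30th percentile of the GC distribution (about one
    third of bins fall below it).  The geometric midpoint between that cutoff
    and the maximum typically sits at an extreme (~95th) percentile, so the
    high cutoff is instead taken at the 90th percentile to leave a usable
    share of high-GC bins.
    """
    q = gc_quantile_report(bins)
    return q["p30"], q["p90"]


def classify_gc_bins(
    bins: Sequence[GCBin],
    low_cut: float = 0.37,
    high_cut: float = 0.47,
) -> Tuple[List[GCBin], Dict[str, IntervalSet]]:
    """Assign low / medium / high GC classes and emit per-class interval sets.

    ``low`` strictly below *low_cut*; ``medium`` inclusive between the
    cutoffs; ``high`` strictly above *high_cut*.  Bins with a missing GC
    fraction keep a missing class and belong to no interval set.
    """
    if not low_cut < high_cut:
        raise ValueError("low_cut must be < high_cut")
    classified: List[GCBin] = []
    per_class: Dict[str, list] = {"low": [], "medium": [], "high": []}
    for b in bins:
        if b.gc_fraction is None:
            cls = None
        elif b.gc_fraction < low_cut:
            cls = "low"
        elif b.gc_fraction > high_cut:
            cls = "high"
        else:
            cls = "medium"
        classified.append(replace(b, gc_class=cls))
        if cls is not None:
            per_class[cls].append((b.contig, b.start, b.end))
    return classified, {cls: IntervalSet(ivs) for cls, ivs in per_class.items()}


def variants_per_bin(cs: Callset, bins: Sequence[GCBin]) -> np.ndarray:
    """Count keys per bin by anchor position (half-open convention).

    Returns an integer array parallel to *bins*.  Keys on contigs that are
    not tiled are ignored.
    """
    index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, b in enumerate(bins):
        index.setdefault(b.contig, ([], [], []))
        index[b.contig][0].append(b.start)
        index[b.contig][1].append(b.end)
        index[b.contig][2].append(i)
    arrays = {}
    for c, (s, e, i) in index.items():
        order = np.argsort(s)
        arrays[c] = (
            np.array(s)[order],
            np.array(e)[order],
            np.array(i)[order],
        )
    counts = np.zeros(len(bins), dtype=np.int64)
    by_contig: Dict[str, list] = {}
    for key in cs.keys:
        by_contig.setdefault(key.contig, []).append(key.pos - 1)
    for contig, positions in by_contig.items():
        if contig not in arrays:
            continue
        starts, ends, idx = arrays[contig]
        pos = np.array(positions, dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        for bin_idx in idx[j[ok]]:
            counts[bin_idx] += 1
    return counts


def spearman_gc_correlation(
    counts: np.ndarray, bins: Sequence[GCBin]
) -> Tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation of per-bin variant counts with GC fraction.

    Bins with missing GC are excluded; requires >= 3 usable bins.  Returns
    ``(None, None)`` with a warning when either input is constant.
    """
    mask = np.array([b.gc_fraction is not None for b in bins])
    if mask.sum() < 3:
        raise ValueError("need at least 3 bins with a defined GC fraction")
    gc = np.array([b.gc_fraction for b, m in zip(bins, mask) if m])
    cnt = np.asarray(counts)[mask]
    if np.all(gc == gc[0]) or np.all(cnt == cnt[0]):
        logger.warning("spearman correlation undefined for constant input")
        return None, None
    rho, p = stats.spearmanr(gc, cnt)
    return float(rho), float(p)


def gc_bins_to_frame(bins: Sequence[GCBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [b.contig for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "gc_fraction": [b.gc_fraction for b in bins],
            "gc_class": [b.gc_class for b in bins],
        }
    )
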