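"""Multi-setup membership structures, Venn partitions and Jaccard concordance.

Given one normalized callset per experimental setup (platform x pipeline) for
the same individual, every variant key in the union is assigned a membership
bit-vector over the k setups.  The Venn partition counts keys per membership
signature; the concordance matrix holds pairwise Jaccard distances
``1 - |A & B| / |A | B|``.  Both are computed per individual and then averaged
arithmetically across the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import Callset, VariantClass, VariantKey

logger = logging.getLogger("concordia.concordance")


class ConfigurationError(ValueError):
    """Inconsistent setup labels or incompatible inputs."""


@dataclass
class MembershipMatrix:
    """Map from variant key to a membership bitmask over ordered setups.

    Bit ``i`` of an entry is set iff the key is present in ``setups[i]``.
    Every entry has at least one bit set (keys come from the union).
    """

    setups: List[str]
    entries: Dict[VariantKey, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.setups)

    def signature_label(self, mask: int) -> str:
        return "".join("1" if mask >> i & 1 else "0" for i in range(self.k))


@dataclass
class VennPartition:
    """Counts of variants per subset-membership signature over k setups."""

    setups: List[str]
    counts: Dict[int, float] = field(default_factory=dict)
    variant_class: Optional[VariantClass] = None

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def signature_label(self, mask: int) -> str:
        return "".join("1" if mask >> i & 1 else "0" for i in range(len(self.setups)))


@dataclass
class ConcordanceMatrix:
    """Symmetric k x k matrix of Jaccard distances with zero diagonal."""

    setups: List[str]
    values: np.ndarray
    variant_class: Optional[VariantClass] = None
    stratum: str = "genome"

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.setups.index(a), self.setups.index(b)])


def _check_setups(callsets: Sequence[Callset]) -> List[str]:
    labels = [cs.setup_label for cs in callsets]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate setup labels: {labels}")
    individuals = {cs.individual_id for cs in callsets}
    if len(individuals) > 1:
        raise ConfigurationError(
            f"callsets span multiple individuals: {sorted(individuals)}"
        )
    return labels


def build_membership(
    callsets: Sequence[Callset], variant_class: Optional[VariantClass] = None
) -> MembershipMatrix:
    """Build the union membership matrix over one individual's callsets."""
    labels = _check_setups(callsets)
    entries: Dict[VariantKey, int] = {}
    for i, cs in enumerate(callsets):
        keys = cs.keys if variant_class is None else cs.keys_of_class(variant_class)
        bit = 1 << i
        for key in keys:
            entries[key] = entries.get(key, 0) | bit
    return MembershipMatrix(setups=labels, entries=entries)


def venn_partition(
    m: MembershipMatrix, variant_class: Optional[VariantClass] = None
) -> VennPartition:
    """Count keys per membership signature; totals conserve the union size."""
    counts: Dict[int, float] = {}
    for mask in m.entries.values():
        counts[mask] = counts.get(mask, 0) + 1
    return VennPartition(setups=list(m.setups), counts=counts, variant_class=variant_class)


def unique_and_full_counts(vp: VennPartition) -> Dict[str, float]:
    """Setup-unique counts, the all-setups intersection, and the remainder.

    ``remainder`` is the union total minus uniques and full intersection, so
    the returned categories always conserve the union size.
    """
    k = len(vp.setups)
    full = (1 << k) - 1
    out: Dict[str, float] = {}
    for i, label in enumerate(vp.setups):
        out[f"unique:{label}"] = float(vp.counts.get(1 << i, 0))
    out["intersection_all"] = float(vp.counts.get(full, 0))
    out["remainder"] = vp.total - sum(out.values())
    return out


def jaccard_distance(a: set, b: set) -> float:
    """``1 - |A & B| / |A | B|``; two empty sets give 0 with a warning."""
    union = len(a | b)
    if union == 0:
        logger.warning("jaccard_distance of two empty sets; returning 0")
        return 0.0
    return 1.0 - len(a & b) / union


def pairwise_jaccard(
    callsets: Sequence[Callset],
    variant_class: Optional[VariantClass] = None,
    stratum: str = "genome",
) -> ConcordanceMatrix:
    """Pairwise Jaccard distance matrix over class-filtered key sets."""
    labels = _check_setups(callsets)
    sets = [
        cs.keys if variant_class is None else cs.keys_of_class(variant_class)
        for cs in callsets
    ]
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = jaccard_distance(sets[i], sets[j])
            values[i, j] = values[j, i] = d
    return ConcordanceMatrix(
        setups=labels, values=values, variant_class=variant_class, stratum=stratum
    )


def average_over_individuals(per_individual: Sequence):
    """Element-wise arithmetic mean of Venn partitions or concordance matrices.

    Inputs must share the same ordered setup list.  Venn means may be
    non-integer; full precision is kept internally.
    """
    if not per_individual:
        raise ConfigurationError("nothing to average")
    first = per_individual[0]
    for other in per_individual[1:]:
        if list(other.setups) != list(first.setups):
            raise ConfigurationError("heterogeneous setup lists")
    n = len(per_individual)
    if isinstance(first, VennPartition):
        signatures = set()
        for vp in per_individual:
            signatures |= set(vp.counts)
        counts = {
            sig: sum(vp.counts.get(sig, 0) for vp in per_individual) / n
            for sig in signatures
        }
        return VennPartition(
            setups=list(first.setups),
            counts=counts,
            variant_class=first.variant_class,
        )
    if isinstance(first, ConcordanceMatrix):
        values = np.mean([cm.values for cm in per_individual], axis=0)
        return ConcordanceMatrix(
            setups=list(first.setups),
            values=values,
            variant_class=first.variant_class,
            stratum=first.stratum,
        )
    raise TypeError(f"cannot average {type(first).__name__}")


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def venn_to_frame(vp: VennPartition) -> pd.DataFrame:
    """One row per signature with per-setup bit columns and the count."""
    rows = []
    for mask in sorted(vp.counts):
        row = {label: (mask >> i) & 1 for i, label in enumerate(vp.setups)}
        row["signature"] = vp.signature_label(mask)
        row["count"] = vp.counts[mask]
        rows.append(row)
    cols = list(vp.setups) + ["signature", "count"]
    return pd.DataFrame(rows, columns=cols)


def concordance_to_frame(cm: ConcordanceMatrix) -> pd.DataFrame:
    """Long format: setup_a, setup_b, stratum, class, jaccard (upper triangle)."""
    rows = []
    for i, a in enumerate(cm.setups):
        for j in range(i + 1, len(cm.setups)):
            rows.append(
                {
                    "setup_a": a,
                    "setup_b": cm.setups[j],
                    "stratum": cm.stratum,
                    "variant_class": cm.variant_class.value if cm.variant_class else "ALL",
                    "jaccard": float(cm.values[i, j]),
                }
            )
    return pd.DataFrame(rows)
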