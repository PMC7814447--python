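"""Cohort merging, MAF / exact HWE statistics and rare-variant stratification.

Per-individual callsets for one setup are merged into cohort-level genotype
counts.  The VCF representation is sparse — individuals without a record at a
site are counted as homozygous reference ("missing as reference"), and
missing genotypes at called sites are folded into the reference class as
well.  Sites are then scored with the minor allele frequency and the exact
conditional Hardy-Weinberg test; sites failing both the MAF < 0.05 and
HWE p < 0.05 criteria form the rare-variant set that is stratified by
high/low confidence intervals and summarized by read depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .tracks import GenomeIndex, IntervalSet
from .variants import Callset, VariantClass, VariantKey

logger = logging.getLogger("concordia.cohort")


@dataclass
class CohortSite:
    """Alt-allele-based genotype counts for one variant key across a cohort."""

    key: VariantKey
    n_rr: int
    n_ra: int
    n_aa: int
    depths: List[int] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_rr + self.n_ra + self.n_aa


class SiteStats(NamedTuple):
    maf: float
    hwe_p: float


def merge_cohort(callsets: Sequence[Callset]) -> List[CohortSite]:
    """Merge one setup's per-individual callsets into cohort genotype counts.

    One :class:`CohortSite` per distinct key; individuals lacking the key (or
    with a missing genotype at it) are counted in ``n_rr``.  Per-carrier read
    depths are collected for downstream depth summaries.
    """
    ids = [cs.individual_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate individual ids in cohort: {ids}")
    n_ind = len(callsets)
    counts: Dict[VariantKey, CohortSite] = {}
    for cs in callsets:
        for key in cs.keys:
            site = counts.get(key)
            if site is None:
                site = counts[key] = CohortSite(key=key, n_rr=n_ind, n_ra=0, n_aa=0)
            depth, genotype = cs.attrs.get(key, (None, None))
            if genotype == (1, 1):
                site.n_aa += 1
                site.n_rr -= 1
            elif genotype == (0, 1):
                site.n_ra += 1
                site.n_rr -= 1
            # missing genotype stays folded into n_rr
            if depth is not None:
                site.depths.append(int(depth))
    return sorted(counts.values(), key=lambda s: s.key)


def compute_maf(site: CohortSite) -> float:
    """Minor allele frequency ``min(f, 1 - f)`` with ``f`` the alt frequency."""
    if site.n_total <= 0:
        raise ValueError("n_total must be positive")
    f = (site.n_ra + 2 * site.n_aa) / (2 * site.n_total)
    return min(f, 1.0 - f)


def hwe_exact_test(n_rr: int, n_ra: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the sample size and the minor-allele count and sums the
    probabilities of every heterozygote count whose conditional probability
    does not exceed that of the observed configuration (probability-ordering
    two-sided test, no mid-p correction).  Returns a p-value in (0, 1];
    monomorphic sites give exactly 1.
    """
    if min(n_rr, n_ra, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_rr + n_ra + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    alt = 2 * n_aa + n_ra
    rare = min(alt, 2 * n - alt)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log conditional weight: n! / (n_ra! n_aa! n_rr!) * 2^n_ra, with the
    # hom counts implied by the het count and the fixed minor-allele total
    rare_hom = (rare - hets) // 2
    common_hom = n - hets - rare_hom
    logw = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logw -= logsumexp(logw)
    probs = np.exp(logw)
    observed = int(n_ra)
    p_obs = probs[np.searchsorted(hets, observed)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def site_stats(site: CohortSite) -> SiteStats:
    return SiteStats(
        maf=compute_maf(site),
        hwe_p=hwe_exact_test(site.n_rr, site.n_ra, site.n_aa),
    )


@dataclass
class RareVariantSet:
    """Keys failing the MAF and HWE criteria, with stats and carrier depths."""

    keys: set
    maf_threshold: float
    hwe_threshold: float
    stats: Dict[VariantKey, SiteStats] = field(default_factory=dict)
    depths: Dict[VariantKey, List[int]] = field(default_factory=dict)
    confidence: Dict[VariantKey, str] = field(default_factory=dict)

    def class_counts(self) -> Dict[VariantClass, int]:
        out: Dict[VariantClass, int] = {}
        for key in self.keys:
            out[key.variant_class] = out.get(key.variant_class, 0) + 1
        return out


def rare_hwe_filter(
    sites: Sequence[CohortSite],
    maf_threshold: float = 0.05,
    hwe_threshold: float = 0.05,
    mode: str = "and",
) -> RareVariantSet:
    """Keep sites with ``MAF < maf_threshold`` and ``HWE p < hwe_threshold``.

    Strict inequalities on both criteria.  ``mode="or"`` retains sites
    failing either criterion instead (sensitivity-analysis variant).
    """
    if mode not in ("and", "or"):
        raise ValueError("mode must be 'and' or 'or'")
    rv = RareVariantSet(
        keys=set(), maf_threshold=maf_threshold, hwe_threshold=hwe_threshold
    )
    for site in sites:
        st = site_stats(site)
        passed_maf = st.maf < maf_threshold
        passed_hwe = st.hwe_p < hwe_threshold
        keep = (passed_maf and passed_hwe) if mode == "and" else (passed_maf or passed_hwe)
        if keep:
            rv.keys.add(site.key)
            rv.stats[site.key] = st
            rv.depths[site.key] = list(site.depths)
    return rv


def confidence_stratify(
    rv: RareVariantSet, high_conf: IntervalSet, genome: GenomeIndex
) -> Dict[Tuple[VariantClass, str], int]:
    """Label keys high/low confidence by anchor membership and count strata.

    A key is ``high`` iff its anchor base lies in the high-confidence track;
    everything else (the track's complement over the genome) is ``low``.
    Counts are returned per (variant class, confidence) and conserve ``|rv|``.
    """
    counts: Dict[Tuple[VariantClass, str], int] = {}
    for key in rv.keys:
        label = "high" if high_conf.contains(key.contig, key.pos - 1) else "low"
        rv.confidence[key] = label
        stratum = (key.variant_class, label)
        counts[stratum] = counts.get(stratum, 0) + 1
    return counts


def depth_distribution(
    rv: RareVariantSet, stratum: Tuple[VariantClass, str]
) -> Dict[str, Optional[float]]:
    """Five-number summary of carrier depths for one (class, confidence) stratum.

    Missing depths are excluded; ``n`` reports the number of depth values
    summarized.  An empty stratum yields an all-``None`` summary.
    """
    vclass, label = stratum
    values: List[int] = []
    for key in rv.keys:
        if key.variant_class is vclass and rv.confidence.get(key) == label:
            values.extend(rv.depths.get(key, ()))
    if not values:
        return {"min": None, "q1": None, "median": None, "q3": None, "max": None, "n": 0}
    arr = np.array(values, dtype=float)
    return {
        "min": float(arr.min()),
        "q1": float(np.quantile(arr, 0.25)),
        "median": float(np.quantile(arr, 0.50)),
        "q3": float(np.quantile(arr, 0.75)),
        "max": float(arr.max()),
        "n": int(len(arr)),
    }


def cohort_to_frame(
    sites: Sequence[CohortSite], rv: Optional[RareVariantSet] = None
) -> pd.DataFrame:
    """Cohort-level table: key, class, genotype counts, maf, hwe_p, confidence."""
    rows = []
    for site in sites:
        st = site_stats(site)
        key = site.key
        rows.append(
            {
                "contig": key.contig,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "variant_class": key.variant_class.value,
                "n_rr": site.n_rr,
                "n_ra": site.n_ra,
                "n_aa": site.n_aa,
                "maf": st.maf,
                "hwe_p": st.hwe_p,
                "confidence": rv.confidence.get(key) if rv else None,
            }
        )
    return pd.DataFrame(rows)
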