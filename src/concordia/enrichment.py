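"""Monte-Carlo null model for setup-unique and all-setups-concordant variants.

The null hypothesis: every setup calls its observed number of variants by
drawing uniformly at random, without replacement and independently of the
other setups, from a common base population of ``N`` variants.  Under that
null the expected number of variants unique to setup *i* and of variants seen
by every setup follows from elementary set algebra; simulation of the null
provides empirical 95% confidence intervals for observed/expected ratios and
a chi-square goodness-of-fit comparison of the observed category counts.

Simulation is performed on subset-signature cells rather than on individual
items: adding one setup to ``j`` already-drawn setups splits each of the
``2^j`` signature cells with a multivariate hypergeometric draw, which is
distributionally identical to drawing an explicit uniform subset but runs in
``O(reps * k * 2^k)`` regardless of ``N``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("concordia.enrichment")

INTERSECTION = "intersection_all"
REMAINDER = "remainder"


@dataclass
class EnrichmentConfig:
    """Base-population size, per-setup draw sizes, and simulation settings."""

    N: int
    n_by_setup: Dict[str, int]
    reps: int = 1000
    seed: int = 20210119

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for label, n in self.n_by_setup.items():
            if not 0 < n <= self.N:
                raise ValueError(
                    f"draw size for {label!r} must be in (0, N]; got {n} with N={self.N}"
                )

    @property
    def labels(self) -> List[str]:
        return list(self.n_by_setup)

    def categories(self) -> List[str]:
        return [f"unique:{lab}" for lab in self.labels] + [INTERSECTION]


@dataclass
class NullDistribution:
    """Per-category vectors of simulated counts (length ``reps``)."""

    cfg: EnrichmentConfig
    counts: Dict[str, np.ndarray]

    def mean(self) -> Dict[str, float]:
        return {cat: float(v.mean()) for cat, v in self.counts.items()}


@dataclass
class EnrichmentResult:
    categories: List[str]
    observed: Dict[str, float]
    expected_mean: Dict[str, float]
    ratio: Dict[str, Optional[float]]
    ci: Dict[str, tuple]
    chisq_stat: float
    chisq_p: float
    dof: int


def simulate_null(cfg: EnrichmentConfig) -> NullDistribution:
    """Simulate the null distribution of unique / intersection counts.

    Deterministic given ``cfg.seed``.  Each rep draws, for every setup, a
    uniform random subset of its observed size from the ``N`` base variants
    and records the per-setup unique counts, the all-setups intersection, and
    the remainder ``N - sum(uniques) - intersection``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.labels
    k = len(labels)
    full = (1 << k) - 1
    reps = cfg.reps
    out = {cat: np.zeros(reps, dtype=np.int64) for cat in cfg.categories()}
    out[REMAINDER] = np.zeros(reps, dtype=np.int64)
    for rep in range(reps):
        cells: Dict[int, int] = {0: cfg.N}
        for i, label in enumerate(labels):
            bit = 1 << i
            masks = list(cells)
            sizes = np.array([cells[m] for m in masks], dtype=np.int64)
            taken = rng.multivariate_hypergeometric(sizes, cfg.n_by_setup[label])
            new_cells: Dict[int, int] = {}
            for mask, size, t in zip(masks, sizes, taken):
                if t:
                    new_cells[mask | bit] = new_cells.get(mask | bit, 0) + int(t)
                rest = int(size - t)
                if rest:
                    new_cells[mask] = new_cells.get(mask, 0) + rest
            cells = new_cells
        special = 0
        for i, label in enumerate(labels):
            u = cells.get(1 << i, 0)
            out[f"unique:{label}"][rep] = u
            special += u
        inter = cells.get(full, 0)
        out[INTERSECTION][rep] = inter
        out[REMAINDER][rep] = cfg.N - special - inter
    return NullDistribution(cfg=cfg, counts=out)


def closed_form_expected(cfg: EnrichmentConfig) -> Dict[str, float]:
    """Exact expected category counts under the null.

    Because each setup draws an independent uniform subset of fixed size, any
    single base variant belongs to setup *i* with probability ``p_i = n_i/N``
    independently across setups, so by linearity of expectation::

        E[unique_i]          = N * p_i * prod_{j != i} (1 - p_j)
        E[intersection_all]  = N * prod_i p_i
    """
    p = {lab: n / cfg.N for lab, n in cfg.n_by_setup.items()}
    out: Dict[str, float] = {}
    for lab in cfg.labels:
        val = p[lab]
        for other in cfg.labels:
            if other != lab:
                val *= 1.0 - p[other]
        out[f"unique:{lab}"] = cfg.N * val
    out[INTERSECTION] = cfg.N * math.prod(p.values())
    out[REMAINDER] = cfg.N - sum(out.values())
    return out


def enrichment_test(
    observed: Dict[str, float], null: NullDistribution
) -> EnrichmentResult:
    """Compare observed category counts against the simulated null.

    * ``ratio`` = observed / mean simulated count (missing when the mean is 0).
    * 95% CI = 2.5th/97.5th percentiles of the per-rep ratios
      ``observed / expected_rep`` (reps with a zero expected count are
      excluded with a warning).
    * chi-square goodness of fit of the observed counts against the null
      means over the k unique categories, the full intersection, and the
      remainder category, which makes both totals sum to ``N``.
    """
    cfg = null.cfg
    cats = cfg.categories()
    missing = [c for c in cats if c not in observed]
    if missing:
        raise ValueError(f"observed counts missing categories: {missing}")
    obs = {c: float(observed[c]) for c in cats}
    obs[REMAINDER] = cfg.N - sum(obs.values())
    all_cats = cats + [REMAINDER]

    expected_mean = {c: float(null.counts[c].mean()) for c in all_cats}
    ratio: Dict[str, Optional[float]] = {}
    ci: Dict[str, tuple] = {}
    for c in all_cats:
        reps = null.counts[c].astype(float)
        nonzero = reps[reps > 0]
        if expected_mean[c] == 0:
            ratio[c] = None
            ci[c] = (None, None)
            logger.warning("category %s has zero expected count in every rep", c)
            continue
        ratio[c] = obs[c] / expected_mean[c]
        if len(nonzero) < len(reps):
            logger.warning(
                "category %s: %d/%d reps with zero expected count excluded from CI",
                c,
                len(reps) - len(nonzero),
                len(reps),
            )
        per_rep = obs[c] / nonzero
        ci[c] = (
            float(np.percentile(per_rep, 2.5)),
            float(np.percentile(per_rep, 97.5)),
        )

    usable = [c for c in all_cats if expected_mean[c] > 0]
    chisq = float(
        sum((obs[c] - expected_mean[c]) ** 2 / expected_mean[c] for c in usable)
    )
    dof = len(usable) - 1
    chisq_p = float(stats.chi2.sf(chisq, dof)) if dof > 0 else float("nan")
    return EnrichmentResult(
        categories=all_cats,
        observed=obs,
        expected_mean=expected_mean,
        ratio=ratio,
        ci=ci,
        chisq_stat=chisq,
        chisq_p=chisq_p,
        dof=dof,
    )


def result_to_frame(res: EnrichmentResult, paper_style: bool = False) -> pd.DataFrame:
    """Tabular report mirroring the observed/expected/ratio (CI) layout.

    With ``paper_style`` counts are rounded to integers and ratios/CIs to two
    decimals; otherwise full precision is kept.
    """
    rows = []
    for cat in res.categories:
        lo, hi = res.ci[cat]
        row = {
            "category": cat,
            "observed": res.observed[cat],
            "expected": res.expected_mean[cat],
            "ratio": res.ratio[cat],
            "ci_low": lo,
            "ci_high": hi,
        }
        if paper_style:
            row["observed"] = round(row["observed"])
            row["expected"] = round(row["expected"])
            for col in ("ratio", "ci_low", "ci_high"):
                if row[col] is not None:
                    row[col] = round(row[col], 2)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["chisq_stat"] = res.chisq_stat
    frame.attrs["chisq_p"] = res.chisq_p
    frame.attrs["dof"] = res.dof
    return frame
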