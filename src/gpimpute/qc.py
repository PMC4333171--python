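"""Locus quality control and equally spaced panel selection.

Loci are discarded when their minor allele frequency, call rate or
Hardy-Weinberg equilibrium p-value falls below threshold; the defaults are
MAF >= 0.05, call rate >= 95% and HWE p >= 0.01. Lower-density panels are
built from the retained, map-ordered loci by sampling a uniform grid of
indices (or of map positions), which is how evenly spaced 905-, 453- and
201-SNP subsets arise from an 1,809-SNP full panel (masking rates of
roughly 50, 75 and 90%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "PanelSelection",
    "hwe_test",
    "hwe_exact_test",
    "filter_loci",
    "select_equally_spaced",
]


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class PanelSelection:
    """Strictly increasing locus indices of a reduced, evenly spaced panel."""

    selected_indices: np.ndarray
    n_full: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.ndim != 1 or len(idx) == 0:
            raise ValueError("panel must contain at least one locus")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("panel indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= self.n_full:
            raise ValueError("panel indices out of range")
        object.__setattr__(self, "selected_indices", idx)

    @property
    def n_target(self) -> int:
        return len(self.selected_indices)

    @property
    def masking_rate(self) -> float:
        return 1.0 - self.n_target / self.n_full


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """One-df chi-square goodness-of-fit p-value for Hardy-Weinberg.

    ``n0, n1, n2`` count genotypes with 0, 1 and 2 copies of the counted
    allele. Expected counts come from the sample allele frequency; a
    monomorphic locus fits HWE perfectly (p = 1). No continuity correction.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    nz = expected > 0
    statistic = float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))
    return float(stats.chi2.sf(statistic, df=1))


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p-value (sum of heterozygote-count probabilities <= observed's)."""
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_rare = min(2 * n2 + n1, 2 * n0 + n1)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log-probabilities of each possible het count given allele counts
    from scipy.special import gammaln

    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_homs + 1)
        - gammaln(common_homs + 1)
    )
    logp -= np.logaddexp.reduce(logp)
    probs = np.exp(logp)
    observed = probs[hets == n1][0]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def filter_loci(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None, exact_hwe: bool = False
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply MAF, call-rate and HWE filters; return survivors and a report.

    The report lists, per locus, the three statistics and the first failing
    rule (checked in the order call_rate, maf, hwe; empty string = retained).
    Idempotent: filtering an already-filtered matrix removes nothing.
    """
    t = thresholds or QCThresholds()
    test = hwe_exact_test if exact_hwe else hwe_test
    call_rate = g.call_rate()
    freq = g.allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.empty(g.n_loci)
    for j in range(g.n_loci):
        col = g.codes[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            hwe_p[j] = np.nan
            continue
        hwe_p[j] = test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    fail = np.full(g.n_loci, "", dtype=object)
    fail[(fail == "") & (np.nan_to_num(maf, nan=0.0) < t.maf_min)] = "maf"
    fail[(fail == "") & (np.nan_to_num(hwe_p, nan=1.0) < t.hwe_alpha)] = "hwe"
    fail[call_rate < t.call_rate_min] = "call_rate"  # checked first: overrides
    report = pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "failed_rule": fail,
        }
    )
    keep = np.flatnonzero(fail == "")
    return g.subset_loci(keep), report


def select_equally_spaced(
    n_available: int,
    n_target: int,
    spacing_basis: str = "index",
    positions: np.ndarray | None = None,
) -> PanelSelection:
    """Evenly spaced panel of ``n_target`` loci out of ``n_available``.

    Index basis (default): indices are ``floor(i * n_available / n_target)``
    for i = 0..n_target-1, so the first locus is always included and e.g.
    201 of 1,809 loci gives exact stride 9. Position basis: nearest loci to
    a uniform grid over the map span.
    """
    if not 1 <= n_target <= n_available:
        raise ValueError("need 1 <= n_target <= n_available")
    if spacing_basis == "index":
        idx = (np.arange(n_target) * n_available) // n_target
    elif spacing_basis == "position":
        if positions is None or len(positions) != n_available:
            raise ValueError("position basis requires per-locus positions")
        pos = np.cumsum(np.concatenate([[0.0], np.maximum(np.diff(positions), 0.0)]))
        grid = pos[0] + (pos[-1] - pos[0]) * np.arange(n_target) / n_target
        idx = np.searchsorted(pos, grid)
        idx = np.minimum(idx, n_available - 1)
        idx = np.unique(idx)
        while len(idx) < n_target:  # fill gaps left by duplicate grid hits
            missing = np.setdiff1d(np.arange(n_available), idx)
            idx = np.sort(np.append(idx, missing[: n_target - len(idx)]))
    else:
        raise ValueError(f"unknown spacing basis {spacing_basis!r}")
    return PanelSelection(selected_indices=idx, n_full=n_available)
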