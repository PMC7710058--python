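"""Group statistics for cohort-level learning comparisons.

Two tests mirror the behavioral analysis conventions of this paradigm:

* a paired two-sided Wilcoxon signed-rank test on per-animal L_w vs L_b
  (zero differences dropped before ranking, with the dropped count
  reported; exact null distribution for effective n <= 25 without ties,
  normal approximation with continuity correction otherwise);
* a Kruskal-Wallis omnibus test on performance across conditions, followed
  by tie-corrected Dunn rank post-hoc contrasts with Sidak family-wise
  adjustment, optionally restricted to contrasts against a reference
  condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float
    p_value: float
    n: int
    n_effective: int
    n_dropped_zero: int
    method: str
    pairing: str = "across animals (one pair per animal)"


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    contrasts: list[Contrast]
    degenerate: bool = False


def paired_signed_rank(l_w, l_b, min_n: int = 5) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired L_w / L_b values.

    Pairs with zero difference are dropped before ranking (the classic
    convention); if all differences are zero there is no evidence of any
    difference and p = 1 is reported with n_effective = 0.  Cohorts smaller
    than ``min_n`` are refused as underpowered.
    """
    l_w = np.asarray(l_w, dtype=float)
    l_b = np.asarray(l_b, dtype=float)
    if l_w.shape != l_b.shape or l_w.ndim != 1:
        raise ValueError("l_w and l_b must be equal-length 1-D sequences")
    n = l_w.size
    if n < min_n:
        raise ValueError(f"signed-rank test needs n >= {min_n} pairs, got {n}")
    diffs = l_w - l_b
    nonzero = diffs[diffs != 0]
    n_eff = nonzero.size
    n_dropped = n - n_eff
    if n_eff == 0:
        return SignedRankResult(
            statistic=0.0, p_value=1.0, n=n, n_effective=0,
            n_dropped_zero=n_dropped, method="degenerate (all differences zero)",
        )
    has_ties = np.unique(np.abs(nonzero)).size < n_eff
    if n_eff <= 25 and not has_ties:
        method = "exact"
        res = sps.wilcoxon(nonzero, alternative="two-sided", method="exact")
    else:
        method = "normal approximation with continuity correction"
        res = sps.wilcoxon(
            nonzero, alternative="two-sided", method="approx", correction=True
        )
    return SignedRankResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        n_effective=n_eff,
        n_dropped_zero=n_dropped,
        method=method,
    )


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak family-wise adjustment for m comparisons: 1 - (1 - p)^m."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def _dunn_contrast(
    ranks: np.ndarray,
    groups: np.ndarray,
    a: str,
    b: str,
    tie_term: float,
    n_total: int,
) -> tuple[float, float]:
    ra = ranks[groups == a]
    rb = ranks[groups == b]
    na, nb = ra.size, rb.size
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
    if var <= 0:
        return 0.0, 1.0
    z = (ra.mean() - rb.mean()) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


def group_compare(
    groups: dict[str, "np.ndarray | list[float]"],
    reference: str | None = None,
    min_n: int = 3,
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus Sidak-adjusted Dunn post-hoc contrasts.

    ``groups`` maps condition label to performance values.  With a
    ``reference`` label, contrasts are restricted to reference-vs-other
    pairs; otherwise all pairwise contrasts are tested.  If every value in
    every group is identical the comparison is degenerate and reported as
    such (statistic 0, p = 1, no contrasts).
    """
    if len(groups) < 2:
        raise ValueError("group_compare needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < min_n:
            raise ValueError(f"group {label!r} has n={arr.size} < {min_n}")
    if reference is not None and reference not in arrays:
        raise ValueError(f"reference group {reference!r} not among groups")

    pooled = np.concatenate(list(arrays.values()))
    n_per_group = {k: int(v.size) for k, v in arrays.items()}
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            statistic=0.0, p_value=1.0, n_per_group=n_per_group,
            contrasts=[], degenerate=True,
        )

    h_stat, omnibus_p = sps.kruskal(*arrays.values())

    labels = np.concatenate(
        [np.full(v.size, k, dtype=object) for k, v in arrays.items()]
    )
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))

    keys = list(arrays)
    if reference is not None:
        pairs = [(reference, k) for k in keys if k != reference]
    else:
        pairs = [(keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    m = len(pairs)
    contrasts = []
    for a, b in pairs:
        z, p_raw = _dunn_contrast(ranks, labels, a, b, tie_term, n_total)
        contrasts.append(
            Contrast(group_a=a, group_b=b, z=z, p_raw=p_raw, p_adjusted=sidak_adjust(p_raw, m))
        )
    return GroupComparison(
        statistic=float(h_stat),
        p_value=float(omnibus_p),
        n_per_group=n_per_group,
        contrasts=contrasts,
    )
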