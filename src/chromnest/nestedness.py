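"""Normalized cross-scale nestedness of community pairs.

Two communities detected at different resolutions share some number S of
irreducible domains.  Against a null in which each community's domains are
drawn uniformly at random from the n domains of the chromosome, the overlap
follows a hypergeometric law with mean mu = d_i * d_j / n.  The nestedness
score recentres and rescales the observed overlap,

    N = (S - mu) / (Omega * min(d_i, d_j)),

where Omega is chosen so that N = +1 at the maximum achievable overlap
(S = min(d_i, d_j), full nesting), N = -1 at the minimum achievable overlap
(max(0, d_i + d_j - n), complete segregation) and N = 0 at the random
expectation.  A one-tailed exact p-value from the same hypergeometric null
(threshold 0.025 by default) separates significant from random overlap.

All probabilities are computed in log-factorial arithmetic so that
chromosome-scale domain counts (hundreds) pose no overflow risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_extraction import MembershipTable

__all__ = [
    "OverlapRecord",
    "expected_overlap",
    "nestedness_score",
    "overlap_pmf",
    "overlap_pvalue",
    "pairwise_nestedness",
    "nestedness_summary",
    "records_to_frame",
]

SIGNIFICANCE_THRESHOLD = 0.025


@dataclass
class OverlapRecord:
    """One community pair across scales and its overlap statistics."""

    gamma_i: float
    comm_i: int
    gamma_j: float
    comm_j: int
    d_i: int
    d_j: int
    n: int
    S: int
    mu: float
    omega: float
    N: float
    p: float
    significant: bool
    degenerate: bool = False  # Omega * min(d) == 0: no nesting information


def _check_triple(d_i: int, d_j: int, n: int) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= d_i <= n and 0 <= d_j <= n):
        raise ValueError(f"community sizes ({d_i}, {d_j}) must lie in [0, n={n}]")


def _feasible_range(d_i: int, d_j: int, n: int) -> tuple[int, int]:
    return max(0, d_i + d_j - n), min(d_i, d_j)


def _log_binom(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def overlap_pmf(k: int, d_i: int, d_j: int, n: int) -> float:
    """Probability that two random communities share exactly k domains.

    Exact hypergeometric probability

        P(S = k) = C(n,k) C(n-k, d_j-k) C(n-d_j, d_i-k) / (C(n,d_j) C(n,d_i)),

    evaluated in log space.  Infeasible k returns 0 by convention.
    """
    _check_triple(d_i, d_j, n)
    lo, hi = _feasible_range(d_i, d_j, n)
    if k < lo or k > hi:
        return 0.0
    log_p = (
        _log_binom(n, k)
        + _log_binom(n - k, d_j - k)
        + _log_binom(n - d_j, d_i - k)
        - _log_binom(n, d_j)
        - _log_binom(n, d_i)
    )
    return math.exp(log_p)


def expected_overlap(d_i: int, d_j: int, n: int) -> float:
    """Mean random overlap mu between two communities.

    Evaluated as the explicit first-moment sum over the overlap distribution;
    analytically this equals d_i * d_j / n.
    """
    _check_triple(d_i, d_j, n)
    lo, hi = _feasible_range(d_i, d_j, n)
    return float(sum(k * overlap_pmf(k, d_i, d_j, n) for k in range(max(lo, 1), hi + 1)))


def nestedness_score(S: int, d_i: int, d_j: int, n: int) -> float:
    """Normalized nestedness N in [-1, 1] for an observed overlap S.

    The normalization Omega depends on the direction of the deviation:
    for S > mu it is the headroom to full nesting; for S < mu it is the
    headroom to the minimum achievable overlap, which itself depends on
    whether the communities could in principle be disjoint (d_i + d_j <= n)
    or must intersect (d_i + d_j > n).  S == mu gives 0.
    """
    _check_triple(d_i, d_j, n)
    lo, hi = _feasible_range(d_i, d_j, n)
    if not (lo <= S <= hi):
        raise ValueError(f"overlap S={S} infeasible for (d_i={d_i}, d_j={d_j}, n={n})")
    mu = d_i * d_j / n
    dmin = min(d_i, d_j)
    if S == mu:
        return 0.0
    if S > mu:
        omega = (dmin - mu) / dmin
    elif d_i + d_j - n < 0:
        omega = mu / dmin
    else:
        omega = (mu - (d_i + d_j - n)) / dmin
    denom = omega * dmin
    if denom == 0:
        return 0.0  # degenerate: no room on this side of mu
    return (S - mu) / denom


def _omega(S: int, d_i: int, d_j: int, n: int) -> float:
    mu = d_i * d_j / n
    dmin = min(d_i, d_j)
    if dmin == 0:
        return 0.0
    if S > mu:
        return (dmin - mu) / dmin
    if d_i + d_j - n < 0:
        return mu / dmin
    return (mu - (d_i + d_j - n)) / dmin


def overlap_pvalue(S_obs: int, d_i: int, d_j: int, n: int) -> float:
    """One-tailed exact p-value for an observed overlap.

    Lower tail (sum over k <= S_obs) when S_obs is at or below the mean,
    upper tail (k >= S_obs) when above; computed by summing the exact pmf
    over the feasible range.
    """
    _check_triple(d_i, d_j, n)
    lo, hi = _feasible_range(d_i, d_j, n)
    if not (lo <= S_obs <= hi):
        raise ValueError(f"overlap S={S_obs} infeasible for (d_i={d_i}, d_j={d_j}, n={n})")
    mu = d_i * d_j / n
    if S_obs <= mu:
        ks = range(lo, S_obs + 1)
    else:
        ks = range(S_obs, hi + 1)
    return float(min(1.0, sum(overlap_pmf(k, d_i, d_j, n) for k in ks)))


def _make_record(
    key_i: tuple[float, int],
    key_j: tuple[float, int],
    set_i: frozenset,
    set_j: frozenset,
    n: int,
    threshold: float,
) -> OverlapRecord:
    d_i, d_j = len(set_i), len(set_j)
    S = len(set_i & set_j)
    mu = d_i * d_j / n if n else 0.0
    dmin = min(d_i, d_j)
    omega = _omega(S, d_i, d_j, n)
    degenerate = omega * dmin == 0  # +-1 unattainable on this side of mu
    N = nestedness_score(S, d_i, d_j, n)
    p = overlap_pvalue(S, d_i, d_j, n)
    return OverlapRecord(
        gamma_i=key_i[0],
        comm_i=key_i[1],
        gamma_j=key_j[0],
        comm_j=key_j[1],
        d_i=d_i,
        d_j=d_j,
        n=n,
        S=S,
        mu=mu,
        omega=omega,
        N=N,
        p=p,
        significant=p <= threshold,
        degenerate=degenerate,
    )


def pairwise_nestedness(
    mt: MembershipTable,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[OverlapRecord]:
    """Overlap statistics for every community pair at different resolutions.

    Communities at the same resolution partition the domains and never
    overlap by construction, so only cross-resolution pairs are scored.
    ``n`` is the total domain count of the sweep.
    """
    gammas = mt.gammas
    if gammas.size < 2:
        raise ValueError("need at least 2 gamma levels")
    n = int(mt.domain_ids.size)
    # community -> domain set per gamma level
    level_sets: list[list[tuple[tuple[float, int], frozenset]]] = []
    for g in gammas:
        sub = mt.communities_at(g)
        sets = [
            ((float(g), int(c)), frozenset(grp["domain_id"].tolist()))
            for c, grp in sub.groupby("community_id")
        ]
        level_sets.append(sorted(sets, key=lambda t: t[0]))
    records = []
    for a in range(len(gammas)):
        for b in range(a + 1, len(gammas)):
            for key_i, set_i in level_sets[a]:
                for key_j, set_j in level_sets[b]:
                    records.append(_make_record(key_i, key_j, set_i, set_j, n, threshold))
    return records


def nestedness_summary(records: list[OverlapRecord], bins: int = 40) -> dict:
    """Histogram of N with the +-1 peaks kept in their own closed bins,
    per-bin significant fractions, and overall means with/without the -1 peak.
    """
    if not records:
        raise ValueError("no overlap records to summarize")
    N = np.array([r.N for r in records])
    sig = np.array([r.significant for r in records])
    at_minus1 = np.isclose(N, -1.0, atol=1e-12)
    at_plus1 = np.isclose(N, 1.0, atol=1e-12)
    interior = ~at_minus1 & ~at_plus1
    edges = np.linspace(-1.0, 1.0, bins + 1)
    hist, _ = np.histogram(N[interior], bins=edges)
    sig_hist, _ = np.histogram(N[interior & sig], bins=edges)
    with np.errstate(invalid="ignore"):
        frac_sig = np.where(hist > 0, sig_hist / np.maximum(hist, 1), np.nan)
    mean_all = float(N.mean())
    mean_wo_minus1 = float(N[~at_minus1].mean()) if (~at_minus1).any() else math.nan
    return {
        "bin_edges": edges,
        "counts": hist,
        "frac_significant": frac_sig,
        "count_minus1": int(at_minus1.sum()),
        "count_plus1": int(at_plus1.sum()),
        "count_minus1_significant": int((at_minus1 & sig).sum()),
        "count_plus1_significant": int((at_plus1 & sig).sum()),
        "mean_N": mean_all,
        "mean_N_without_minus1_peak": mean_wo_minus1,
        "n_records": len(records),
        "frac_significant_overall": float(sig.mean()),
    }


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    """Tabulate overlap records (one row per community pair)."""
    return pd.DataFrame(
        {
            "gamma_i": [r.gamma_i for r in records],
            "comm_i": [r.comm_i for r in records],
            "gamma_j": [r.gamma_j for r in records],
            "comm_j": [r.comm_j for r in records],
            "d_i": [r.d_i for r in records],
            "d_j": [r.d_j for r in records],
            "n": [r.n for r in records],
            "S": [r.S for r in records],
            "mu": [r.mu for r in records],
            "N": [r.N for r in records],
            "p": [r.p for r in records],
            "significant": [r.significant for r in records],
        }
    )


def records_to_tsv(records: list[OverlapRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
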