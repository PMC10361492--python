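"""Chromatin-state enrichment of 3D communities and group-wise nestedness.

Communities are annotated with a 15-state chromatin segmentation (ChromHMM-
style states S1..S15: promoters, enhancers, insulator, transcribed,
repressed, heterochromatin, repetitive).  For each community and state, the
observed number of state peaks starting inside the community is compared with
the chromosome-wide expectation under sampling without replacement (exact
hypergeometric test, two-sided as twice the smaller tail).  The 15 tests per
community are corrected with Benjamini-Hochberg at FDR 0.05, and enriched
states map the community into up to four coarse groups:

    A: active promoters (S1-S2)     B: enhancers (S4-S7)
    C: transcribed regions (S9-S11) D: heterochromatin (S3, S12-S15)

S8 (insulator) belongs to no group.  Group labels feed two summaries: the
nestedness distribution of community pairs by group combination, and the
per-community modularity contribution M_c (which sums to the global M),
rescaled by community size to remove the linear size trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .community_detection import NullModel, Partition
from .contact_data import ContactMatrix
from .domain_extraction import Domain, MembershipTable
from .nestedness import OverlapRecord

__all__ = [
    "STATES",
    "STATE_GROUPS",
    "ChromatinTrack",
    "EnrichmentRecord",
    "GroupLabel",
    "count_peak_starts",
    "hypergeom_enrichment",
    "bh_adjust",
    "enrich_communities",
    "group_nestedness",
    "community_modularity",
]

STATES = tuple(f"S{i}" for i in range(1, 16))

STATE_GROUPS: dict[str, tuple[str, ...]] = {
    "A": ("S1", "S2"),
    "B": ("S4", "S5", "S6", "S7"),
    "C": ("S9", "S10", "S11"),
    "D": ("S3", "S12", "S13", "S14", "S15"),
}
# S8 (insulator) maps to no group.
_STATE_TO_GROUPS = {
    s: tuple(g for g, members in STATE_GROUPS.items() if s in members) for s in STATES
}


@dataclass
class ChromatinTrack:
    """Chromatin-state peak intervals (BED-like, 0-based half-open)."""

    peaks: pd.DataFrame  # columns: chrom, start, end, state

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "state"}
        if not req <= set(self.peaks.columns):
            raise ValueError(f"track needs columns {req}")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("malformed peak: start >= end")
        bad = set(self.peaks["state"]) - set(STATES)
        if bad:
            raise ValueError(f"unknown chromatin states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.peaks)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ChromatinTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "state"],
            usecols=[0, 1, 2, 3],
        )
        return cls(df)

    def to_bed(self, path: str | Path) -> None:
        self.peaks[["chrom", "start", "end", "state"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class EnrichmentRecord:
    """One community x state hypergeometric test."""

    gamma: float
    community: int
    state: str
    k: int  # observed peak starts in the community
    n_comm: int  # community total peak count
    K: int  # chromosome-wide peaks of this state
    N_tot: int  # chromosome-wide total peaks
    expected: float  # n_comm * K / N_tot
    p_raw: float
    p_adj: float = np.nan
    status: str = "none"  # enriched | depleted | none


@dataclass
class GroupLabel:
    """Coarse chromatin-group membership of a community (possibly plural)."""

    gamma: float
    community: int
    groups: frozenset = field(default_factory=frozenset)
    degenerate: bool = False  # community had zero peaks: no tests possible


def count_peak_starts(
    track: ChromatinTrack, community_bins: set[int] | np.ndarray, bin_size: int
) -> dict[str, int]:
    """Count peaks per state whose *start* falls in the community's bins.

    Counting starts (rather than overlap) gives every peak exactly one owner
    even when it crosses a community border.
    """
    bins = set(int(b) for b in community_bins)
    counts = dict.fromkeys(STATES, 0)
    start_bins = (track.peaks["start"] // bin_size).astype(int)
    for state, sb in zip(track.peaks["state"], start_bins):
        if int(sb) in bins:
            counts[state] += 1
    return counts


def hypergeom_enrichment(k: int, n_comm: int, K: int, N_tot: int) -> tuple[float, float, str]:
    """Exact two-sided hypergeometric test of a community's state content.

    Draws: ``n_comm`` peaks from a chromosome with ``K`` peaks of the state
    among ``N_tot`` total.  Returns ``(expected, p_raw, direction)`` with the
    two-sided p computed as twice the smaller tail, capped at 1.
    """
    if not (0 <= k <= n_comm <= N_tot and 0 <= K <= N_tot):
        raise ValueError(f"inconsistent totals: k={k}, n_comm={n_comm}, K={K}, N_tot={N_tot}")
    lo = max(0, n_comm - (N_tot - K))
    hi = min(n_comm, K)
    if not lo <= k <= hi:
        raise ValueError(f"observed k={k} infeasible for (n_comm={n_comm}, K={K}, N_tot={N_tot})")
    expected = n_comm * K / N_tot
    rv = hypergeom(N_tot, K, n_comm)
    lower = float(rv.cdf(k))
    upper = float(rv.sf(k - 1))
    p = min(1.0, 2.0 * min(lower, upper))
    direction = "enriched" if k > expected else "depleted"
    return expected, p, direction


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, reject)`` where ``reject`` marks adjusted p <= fdr.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return p_adj, reject


def enrich_communities(
    track: ChromatinTrack,
    mt: MembershipTable,
    domains: list[Domain],
    bin_size: int,
    fdr: float = 0.05,
    per_community_correction: bool = True,
) -> tuple[list[EnrichmentRecord], list[GroupLabel]]:
    """Test every community at every resolution against all 15 states.

    A community's genomic footprint is the union of its member domains' bins
    at that resolution.  BH correction runs across the 15 states within each
    community (or chromosome-wide across all tests when
    ``per_community_correction=False``).
    """
    chrom_counts = track.peaks["state"].value_counts().to_dict()
    K_by_state = {s: int(chrom_counts.get(s, 0)) for s in STATES}
    N_tot = len(track)
    dom_by_id = {d.id: d for d in domains}

    records: list[EnrichmentRecord] = []
    labels: list[GroupLabel] = []
    for g in mt.gammas:
        sub = mt.communities_at(g)
        for comm, grp in sub.groupby("community_id"):
            bins: set[int] = set()
            for did in grp["domain_id"]:
                d = dom_by_id[int(did)]
                bins.update(range(d.start_bin, d.end_bin))
            counts = count_peak_starts(track, bins, bin_size)
            n_comm = sum(counts.values())
            if n_comm == 0:
                labels.append(
                    GroupLabel(gamma=float(g), community=int(comm), degenerate=True)
                )
                continue
            comm_records = []
            for s in STATES:
                expected, p_raw, direction = hypergeom_enrichment(
                    counts[s], n_comm, K_by_state[s], N_tot
                )
                comm_records.append(
                    EnrichmentRecord(
                        gamma=float(g),
                        community=int(comm),
                        state=s,
                        k=counts[s],
                        n_comm=n_comm,
                        K=K_by_state[s],
                        N_tot=N_tot,
                        expected=expected,
                        p_raw=p_raw,
                        status=direction,
                    )
                )
            if per_community_correction:
                p_adj, reject = bh_adjust([r.p_raw for r in comm_records], fdr=fdr)
                for r, pa, rej in zip(comm_records, p_adj, reject):
                    r.p_adj = float(pa)
                    if not rej:
                        r.status = "none"
            records.extend(comm_records)
            if per_community_correction:
                groups = frozenset(
                    g2
                    for r in comm_records
                    if r.status == "enriched"
                    for g2 in _STATE_TO_GROUPS[r.state]
                )
                labels.append(GroupLabel(gamma=float(g), community=int(comm), groups=groups))
    if not per_community_correction:
        p_adj, reject = bh_adjust([r.p_raw for r in records], fdr=fdr)
        seen = {}
        for r, pa, rej in zip(records, p_adj, reject):
            r.p_adj = float(pa)
            if not rej:
                r.status = "none"
            key = (r.gamma, r.community)
            seen.setdefault(key, set())
            if r.status == "enriched":
                seen[key].update(_STATE_TO_GROUPS[r.state])
        labels.extend(
            GroupLabel(gamma=k[0], community=k[1], groups=frozenset(v))
            for k, v in seen.items()
        )
    return records, labels


def group_nestedness(
    records: list[OverlapRecord], labels: list[GroupLabel]
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Split community-pair nestedness values by chromatin-group combination.

    A pair belongs to class XY when it covers both groups: one community
    carries X and the other carries Y (either may carry both).  Within the
    class, ``intersection`` holds pairs where both communities carry X and Y
    simultaneously, ``difference`` the remaining pairs (at least one side
    carries only one of the two labels), and ``union`` their disjoint union.
    Diagonal classes XX require both communities to carry X.
    """
    by_comm = {(l.gamma, l.community): l.groups for l in labels}
    group_names = sorted(STATE_GROUPS)
    out: dict[tuple[str, str], dict[str, list[float]]] = {
        (x, y): {"union": [], "intersection": [], "difference": []}
        for i, x in enumerate(group_names)
        for y in group_names[i:]
    }
    for r in records:
        gi = by_comm.get((r.gamma_i, r.comm_i), frozenset())
        gj = by_comm.get((r.gamma_j, r.comm_j), frozenset())
        if not gi or not gj:
            continue
        for x, y in out:
            covers = (x in gi and y in gj) or (y in gi and x in gj)
            if not covers:
                continue
            out[(x, y)]["union"].append(r.N)
            if {x, y} <= gi and {x, y} <= gj:
                out[(x, y)]["intersection"].append(r.N)
            else:
                out[(x, y)]["difference"].append(r.N)
    return {
        k: {kind: np.asarray(v) for kind, v in d.items()} for k, d in out.items()
    }


def community_modularity(
    m: ContactMatrix,
    null: NullModel,
    partition: Partition,
    mt: MembershipTable | None = None,
) -> pd.DataFrame:
    """Per-community modularity contributions M_c.

    ``M_c = (1/2m) * sum over i != j within community c of (A_ij - gamma P_ij)``;
    summing M_c over communities recovers the global modularity.  When a
    membership table is supplied, community size in domains and the
    size-rescaled ``M_c / size`` are included.
    """
    b = m.counts - partition.gamma * null.p_matrix
    memb = partition.membership
    rows = []
    for c in range(partition.n_communities):
        idx = np.flatnonzero(memb == c)
        blk = b[np.ix_(idx, idx)]
        mc = float((blk.sum() - np.trace(blk)) / null.two_m)
        rows.append({"gamma": partition.gamma, "community": c, "M_c": mc, "n_bins": idx.size})
    df = pd.DataFrame(rows)
    if mt is not None:
        sizes = (
            mt.communities_at(partition.gamma)
            .groupby("community_id")
            .size()
            .rename("n_domains")
        )
        df = df.merge(sizes, left_on="community", right_index=True, how="left")
        df["n_domains"] = df["n_domains"].fillna(0).astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["M_c_rescaled"] = np.where(
                df["n_domains"] > 0, df["M_c"] / df["n_domains"], np.nan
            )
    return df


def group_modularity_medians(
    mc_table: pd.DataFrame, labels: list[GroupLabel]
) -> pd.DataFrame:
    """Median size-rescaled M_c per chromatin group (plus overall)."""
    by_comm = {(l.gamma, l.community): l.groups for l in labels}
    rows = []
    for g in sorted(STATE_GROUPS):
        vals = [
            r["M_c_rescaled"]
            for _, r in mc_table.iterrows()
            if g in by_comm.get((r["gamma"], r["community"]), frozenset())
            and np.isfinite(r.get("M_c_rescaled", np.nan))
        ]
        rows.append({"group": g, "median_rescaled_M_c": float(np.median(vals)) if vals else np.nan, "n": len(vals)})
    overall = mc_table["M_c_rescaled"].dropna()
    rows.append(
        {
            "group": "all",
            "median_rescaled_M_c": float(overall.median()) if len(overall) else np.nan,
            "n": int(len(overall)),
        }
    )
    return pd.DataFrame(rows)
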