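"""Irreducible domains and cross-resolution folding pathways.

Sweeping the resolution parameter gamma yields one partition per scale.  Some
linear DNA stretches are never split by any community border over the whole
sweep; these "irreducible domains" are the natural units for cross-scale
comparison.  Domains are recovered by pooling community borders from every
resolution (plus mask edges) and cutting the chromosome at the union of
borders.

Tracing the community membership of each domain across resolutions produces
its folding pathway; the collection of pathways over all domains forms a
directed multigraph between (gamma, community) nodes whose topology reveals
whether the folding is hierarchical (a proper tree) or not (split-and-reunite
motifs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .community_detection import PartitionSet

__all__ = [
    "Domain",
    "MembershipTable",
    "extract_domains",
    "build_membership",
    "folding_pathways",
    "domains_to_bed",
]


@dataclass(frozen=True)
class Domain:
    """A half-open bin interval [start_bin, end_bin) never split in the sweep.

    Ids are 1-based and sequential along the chromosome, so domain 2 is the
    linear neighbour of domains 1 and 3.
    """

    id: int
    start_bin: int
    end_bin: int

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


class MembershipTable:
    """Tidy (gamma, domain_id, community_id) table.

    Every (gamma, domain_id) pair appears exactly once; all bins of a domain
    share a single community at every resolution by construction.
    """

    COLUMNS = ("gamma", "domain_id", "community_id")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"membership table missing columns {missing}")
        dup = df.duplicated(subset=["gamma", "domain_id"])
        if dup.any():
            raise ValueError("duplicate (gamma, domain_id) rows")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gammas(self) -> np.ndarray:
        return np.sort(self.df["gamma"].unique())

    @property
    def domain_ids(self) -> np.ndarray:
        return np.sort(self.df["domain_id"].unique())

    def communities_at(self, gamma: float) -> pd.DataFrame:
        return self.df[self.df["gamma"] == gamma]

    def domains_of(self, gamma: float, community_id: int) -> list[int]:
        sel = (self.df["gamma"] == gamma) & (self.df["community_id"] == community_id)
        return sorted(self.df.loc[sel, "domain_id"].tolist())

    def to_tsv(self, path: str | Path) -> None:
        # %.17g guarantees gamma round-trips through text exactly
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MembershipTable":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def extract_domains(ps: PartitionSet) -> list[Domain]:
    """Cut the chromosome at the union of community borders over all gammas.

    A border sits between adjacent bins that differ in community id at any
    resolution; masked bins always terminate domains, so domains tile
    exactly the valid bins.
    """
    if len(ps) == 0:
        raise ValueError("empty partition set")
    valid = ps.valid_mask
    n = valid.shape[0]
    # cut[p] == True means a border between bin p-1 and bin p
    cut = np.zeros(n + 1, dtype=bool)
    cut[0] = cut[n] = True
    for p in range(1, n):
        if not valid[p] or not valid[p - 1]:
            cut[p] = True
    for part in ps:
        memb = part.membership
        diff = memb[1:] != memb[:-1]
        cut[1:n][diff] = True
    domains: list[Domain] = []
    starts = np.flatnonzero(cut[:n])
    next_id = 1
    for s in starts:
        if not valid[s]:
            continue  # masked stretch, not a domain
        e = s + 1
        while e < n and not cut[e]:
            e += 1
        domains.append(Domain(id=next_id, start_bin=int(s), end_bin=int(e)))
        next_id += 1
    return domains


def build_membership(ps: PartitionSet, domains: list[Domain]) -> MembershipTable:
    """Record each domain's community at every resolution of the sweep."""
    rows = []
    for part in ps:
        memb = part.membership
        for d in domains:
            ids = np.unique(memb[d.start_bin : d.end_bin])
            if ids.size != 1:
                raise RuntimeError(
                    f"domain {d.id} spans communities {ids} at gamma={part.gamma}; "
                    "domains must come from extract_domains on the same sweep"
                )
            rows.append((part.gamma, d.id, int(ids[0])))
    df = pd.DataFrame(rows, columns=list(MembershipTable.COLUMNS))
    return MembershipTable(df)


def folding_pathways(mt: MembershipTable) -> dict:
    """Cross-resolution folding graph as a node-link document.

    Nodes are (gamma, community) pairs sized by their domain count; a directed
    edge runs from the community a domain occupies at the finer resolution
    gamma_k to the one it occupies at the next coarser gamma_{k-1}, weighted
    by the number of domains making that transition.  In a perfect hierarchy
    every node has exactly one outgoing edge toward the root.
    """
    gammas = mt.gammas
    if gammas.size < 2:
        raise ValueError("folding pathways need at least 2 gamma levels")
    piv = mt.df.pivot(index="domain_id", columns="gamma", values="community_id")
    edges: dict[tuple, int] = {}
    for k in range(len(gammas) - 1, 0, -1):
        g_fine, g_coarse = gammas[k], gammas[k - 1]
        for dom, row in piv.iterrows():
            key = ((float(g_fine), int(row[g_fine])), (float(g_coarse), int(row[g_coarse])))
            edges[key] = edges.get(key, 0) + 1
    node_size: dict[tuple, int] = {}
    for g in gammas:
        for comm, grp in mt.df[mt.df["gamma"] == g].groupby("community_id"):
            node_size[(float(g), int(comm))] = len(grp)
    return {
        "nodes": [
            {"gamma": g, "community": c, "n_domains": s}
            for (g, c), s in sorted(node_size.items())
        ],
        "edges": [
            {
                "from": {"gamma": a[0], "community": a[1]},
                "to": {"gamma": b[0], "community": b[1]},
                "n_domains": w,
            }
            for (a, b), w in sorted(edges.items())
        ],
    }


def domains_to_bed(domains: list[Domain], chrom: str, bin_size: int, path: str | Path) -> None:
    """Write domains as BED (chrom, start_bp, end_bp, domain_id)."""
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{chrom}\t{d.start_bin * bin_size}\t{d.end_bin * bin_size}\t{d.id}\n")
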