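"""Minimal semi-hierarchical chromosome folding model.

The model builds an ideal folding hierarchy and then perturbs it with a
single reshuffling parameter Q:

* **Q = 0 (perfect hierarchy).**  Domains are agglomerated greedily: the
  domain pair with the strongest mean Hi-C interaction merges into a
  superstructure, the merged pair is replaced in the interaction list (size-
  weighted average linkage) and the step repeats until one root remains.
  Cutting the resulting dendrogram at its last few merge events yields
  "rings" of superstructures — organizational levels analogous to the
  resolutions of a community sweep.  In this limit every cross-ring structure
  pair is either fully nested or fully segregated (N = +-1).

* **Q > 0 (semi-hierarchy).**  Within each ring, domains that already sit in
  a superstructure are paired uniformly at random and each pair swaps its
  memberships with probability Q, leaving an odd leftover untouched.  The
  tree backbone is unchanged but memberships delocalize, producing the
  intermediate nestedness values seen in real chromosomes.

Q is fitted by minimizing the two-sample Kolmogorov-Smirnov distance between
model and empirical nestedness values, with the degenerate +-1 values
excluded from both samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_data import ContactMatrix
from .domain_extraction import Domain
from .nestedness import OverlapRecord, _make_record

__all__ = [
    "FoldingTree",
    "QFitResult",
    "domain_interaction",
    "agglomerate",
    "slice_rings",
    "reshuffle",
    "model_nestedness",
    "fit_q",
]

UNASSIGNED = -1


@dataclass
class FoldingTree:
    """Agglomerative merge history over domains.

    ``merge_events[t] = (step, left, right, new, strength)`` where structure
    ids 0..n-1 are the leaf domains (in input order) and each merge creates
    id ``n + step``.  Exactly ``n - 1`` events; the last created id is the
    root containing every domain.
    """

    merge_events: list[tuple[int, int, int, int, float]]
    n_leaves: int
    leaf_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def members(self) -> dict[int, frozenset]:
        """Structure id -> frozenset of leaf indices, for all structures."""
        out: dict[int, frozenset] = {i: frozenset([i]) for i in range(self.n_leaves)}
        for _, left, right, new, _ in self.merge_events:
            out[new] = out[left] | out[right]
        return out


@dataclass
class QFitResult:
    """Grid fit of the reshuffling parameter."""

    q_grid: np.ndarray
    distances: np.ndarray
    q_opt: float
    replicates: int
    seed: int


def domain_interaction(m: ContactMatrix, domains: list[Domain]) -> np.ndarray:
    """Mean contact frequency between every domain pair.

    ``strength[a, b]`` is the arithmetic mean of the contact counts over all
    bin pairs (i in a, j in b) for a != b.  The diagonal is set to 0 and is
    never used by the agglomeration.
    """
    if any(d.n_bins == 0 for d in domains):
        raise ValueError("empty domain")
    nd = len(domains)
    strengths = np.zeros((nd, nd))
    slices = [slice(d.start_bin, d.end_bin) for d in domains]
    for a in range(nd):
        for b in range(a + 1, nd):
            block = m.counts[slices[a], slices[b]]
            strengths[a, b] = strengths[b, a] = block.mean()
    return strengths


def agglomerate(strengths: np.ndarray, sizes: np.ndarray | None = None) -> FoldingTree:
    """Greedy strongest-pair agglomeration of domains into superstructures.

    At each step the structure pair with maximal interaction merges; the new
    structure's interaction with any other structure c is the size-weighted
    mean of its constituents' interactions with c (average linkage, weights =
    total bin counts).  Ties break toward the lexicographically smallest
    (id, id) pair.  With unit sizes this is exactly classic average-linkage
    clustering on similarities.
    """
    strengths = np.asarray(strengths, dtype=float)
    n = strengths.shape[0]
    if strengths.ndim != 2 or strengths.shape[1] != n:
        raise ValueError("strengths must be square")
    if not np.allclose(strengths, strengths.T):
        raise ValueError("strengths must be symmetric")
    if n < 2:
        raise ValueError("need at least 2 domains")
    if sizes is None:
        sizes = np.ones(n)
    sizes = np.asarray(sizes, dtype=float)

    # active structures: id -> (row of current strengths, size)
    cur = {i: i for i in range(n)}  # structure id -> row index in working matrix
    work = strengths.copy()
    np.fill_diagonal(work, -np.inf)
    wsize = {i: float(sizes[i]) for i in range(n)}
    events: list[tuple[int, int, int, int, float]] = []
    active = list(range(n))
    for step in range(n - 1):
        # find max strength among active pairs, smallest (id, id) on ties
        best = None
        best_val = -np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                v = work[cur[a], cur[b]]
                if v > best_val + 1e-15 or (
                    abs(v - best_val) <= 1e-15 and best is not None and (a, b) < best
                ):
                    best_val = v
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        new_id = n + step
        events.append((step, a, b, new_id, float(best_val)))
        # size-weighted average linkage update, written into row of a
        ra, rb = cur[a], cur[b]
        wa, wb = wsize[a], wsize[b]
        merged_row = (wa * work[ra] + wb * work[rb]) / (wa + wb)
        work[ra] = merged_row
        work[:, ra] = merged_row
        work[ra, ra] = -np.inf
        work[rb] = -np.inf
        work[:, rb] = -np.inf
        active.remove(a)
        active.remove(b)
        active.append(new_id)
        cur[new_id] = ra
        wsize[new_id] = wa + wb
    return FoldingTree(merge_events=events, n_leaves=n, leaf_sizes=sizes)


def slice_rings(tree: FoldingTree, n_rings: int = 5) -> list[np.ndarray]:
    """Cut the dendrogram below its last merges into organizational rings.

    Ring r (1-based, innermost first) holds the structure memberships after
    undoing the final ``r - 1`` merges, so ring 1 is the single root and ring
    r contains r structures.  Domains whose structure at a ring is a single
    leaf are marked ``UNASSIGNED`` (they have not yet folded into anything).

    Returns one membership array (length ``n_leaves``) per ring, innermost
    first.
    """
    n_events = len(tree.merge_events)
    if n_rings >= n_events + 1:
        raise ValueError(f"n_rings={n_rings} too large for {n_events} merge events")
    members = tree.members()
    rings = []
    for r in range(1, n_rings + 1):
        # keep merges 0 .. n_events - r; top structures = those never consumed after cut
        kept = tree.merge_events[: n_events - (r - 1)]
        consumed = set()
        created = []
        for _, left, right, new, _ in kept:
            consumed.add(left)
            consumed.add(right)
            created.append(new)
        tops = [s for s in list(range(tree.n_leaves)) + created if s not in consumed]
        memb = np.full(tree.n_leaves, UNASSIGNED, dtype=int)
        for s in tops:
            leaf_set = members[s]
            if len(leaf_set) < 2:
                continue  # lone domain: not yet inside any superstructure
            for leaf in leaf_set:
                memb[leaf] = s
        rings.append(memb)
    return rings


def reshuffle(rings: list[np.ndarray], Q: float, seed: int = 0) -> list[np.ndarray]:
    """Randomly swap domain memberships within each ring with probability Q.

    Per ring independently: the assigned domains are paired uniformly at
    random without replacement; each pair exchanges superstructure
    memberships with probability Q; an odd leftover keeps its membership.
    Structure sizes per ring are preserved exactly.  Bit-reproducible given
    ``seed``.
    """
    if not 0 <= Q <= 1:
        raise ValueError("Q must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for memb in rings:
        new = memb.copy()
        eligible = np.flatnonzero(memb != UNASSIGNED)
        perm = rng.permutation(eligible)
        for t in range(0, len(perm) - 1, 2):
            i, j = perm[t], perm[t + 1]
            if rng.random() < Q:
                new[i], new[j] = new[j], new[i]
        out.append(new)
    return out


def model_nestedness(rings: list[np.ndarray], threshold: float = 0.025) -> list[OverlapRecord]:
    """Nestedness records for all cross-ring superstructure pairs.

    Rings play the role of resolutions; same-ring pairs are never compared.
    For each ring pair, n counts the domains assigned to a superstructure in
    at least one of the two rings (unassigned domains carry no membership
    information and are excluded).
    """
    if len(rings) < 2:
        raise ValueError("need at least 2 rings")
    ring_sets = []
    for level, memb in enumerate(rings):
        sets = {}
        for s in np.unique(memb[memb != UNASSIGNED]):
            sets[int(s)] = frozenset(np.flatnonzero(memb == s).tolist())
        ring_sets.append(sets)
    records = []
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            assigned = np.flatnonzero((rings[a] != UNASSIGNED) | (rings[b] != UNASSIGNED))
            n = int(assigned.size)
            if n == 0:
                continue
            for sa, set_a in sorted(ring_sets[a].items()):
                for sb, set_b in sorted(ring_sets[b].items()):
                    records.append(
                        _make_record(
                            (float(a + 1), sa), (float(b + 1), sb), set_a, set_b, n, threshold
                        )
                    )
    return records


def _interior_values(records: list[OverlapRecord]) -> np.ndarray:
    """Nestedness values strictly inside (-1, 1), excluding records flagged
    degenerate (pairs where +-1 is unattainable carry no nesting signal)."""
    N = np.array([r.N for r in records if not r.degenerate])
    if N.size == 0:
        return N
    return N[np.abs(np.abs(N) - 1.0) > 1e-12]


def _ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import ks_2samp

    return float(ks_2samp(x, y, mode="asymp").statistic)


def fit_q(
    empirical: list[OverlapRecord],
    strengths: np.ndarray,
    q_grid=None,
    replicates: int = 20,
    seed: int = 0,
    n_rings: int = 5,
    sizes: np.ndarray | None = None,
) -> QFitResult:
    """Fit the reshuffling parameter to an empirical nestedness distribution.

    For each Q on the grid, generates ``replicates`` reshuffled model
    realizations from the (fixed) agglomeration backbone, computes the
    two-sample KS distance between model and empirical interior nestedness
    values (+-1 excluded on both sides) and averages; the Q minimizing the
    mean distance wins, ties toward smaller Q.
    """
    if q_grid is None:
        q_grid = np.arange(0.0, 1.0001, 0.05)
    q_grid = np.asarray(q_grid, dtype=float)
    emp = _interior_values(empirical)
    if emp.size == 0:
        raise ValueError("empirical nestedness has no values strictly inside (-1, 1)")
    tree = agglomerate(strengths, sizes=sizes)
    base_rings = slice_rings(tree, n_rings=n_rings)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(replicates * q_grid.size) % (2**31 - 1)
    distances = np.empty(q_grid.size)
    for qi, q in enumerate(q_grid):
        ds = []
        for rep in range(replicates):
            s = int(rep_seeds[qi * replicates + rep])
            rings = reshuffle(base_rings, q, seed=s)
            model = _interior_values(model_nestedness(rings))
            if model.size == 0:
                ds.append(1.0)  # maximally distant: model has no interior mass
            else:
                ds.append(_ks_distance(model, emp))
        distances[qi] = float(np.mean(ds))
    best = int(np.flatnonzero(distances == distances.min())[0])
    return QFitResult(
        q_grid=q_grid,
        distances=distances,
        q_opt=float(q_grid[best]),
        replicates=replicates,
        seed=seed,
    )
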