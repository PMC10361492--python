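"""Synthetic Hi-C matrices and chromatin tracks with planted structure.

The generator emulates the statistical features the analysis assumes, so
every pipeline stage can be exercised without external downloads:

* expected contact counts decay as a power law ``|i - j|**(-alpha)`` with
  alpha = 1 by default (fractal-globule scaling);
* a planted multi-level community hierarchy boosts within-community counts
  multiplicatively, once per shared level, so communities are detectable at
  a resolution matching their depth;
* optional scattering relocates a fraction of bins between sibling
  communities (non-contiguous communities), and an optional reshuffling step
  breaks perfect nesting exactly the way the folding model does;
* counts carry Poisson noise (Hi-C shot noise) when requested;
* chromatin-state peak tracks draw states from per-branch weight vectors so
  chosen branches are enriched in chosen states.

All outputs are bit-reproducible given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_data import ContactMatrix
from .chromatin_enrichment import STATES, ChromatinTrack

__all__ = [
    "SyntheticSpec",
    "synth_hierarchy",
    "synth_contact_matrix",
    "synth_chromatin_track",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic chromosome.

    Defaults give a 256-bin chromosome with a 3-level binary hierarchy,
    3-fold within-community contact boost per shared level (chosen so the
    planted levels unfold across the default resolution grid gamma in
    [0.1, 1]), fractal-globule decay (alpha = 1), Poisson noise on, no
    scattering or reshuffling.
    """

    n_bins: int = 256
    decay_exponent: float = 1.0
    hierarchy_depth: int = 3
    branching: int = 2
    boost: float = 3.0
    scatter_fraction: float = 0.0
    reshuffle_q: float = 0.0
    base_count: float = 100.0
    noise: bool = True
    seed: int = 0
    bin_size: int = 100_000
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.boost < 1:
            raise ValueError("boost must be >= 1")
        if not (0 <= self.scatter_fraction <= 1 and 0 <= self.reshuffle_q <= 1):
            raise ValueError("scatter_fraction and reshuffle_q must be in [0, 1]")
        if self.branching**self.hierarchy_depth > self.n_bins:
            raise ValueError(
                f"branching**depth = {self.branching ** self.hierarchy_depth} exceeds n_bins"
            )


def synth_hierarchy(spec: SyntheticSpec) -> list[np.ndarray]:
    """Planted multi-level membership: one label array per level.

    Level 0 is a single community; level l splits every level-(l-1) community
    into ``branching`` contiguous children.  ``scatter_fraction`` then swaps
    that fraction of bins between sibling communities (size-preserving pair
    swaps, so nestedness combinatorics are untouched), and ``reshuffle_q``
    applies the folding-model swap procedure within each level.
    """
    rng = np.random.default_rng(spec.seed)
    levels = [np.zeros(spec.n_bins, dtype=int)]
    for lvl in range(1, spec.hierarchy_depth + 1):
        parent = levels[-1]
        child = np.empty(spec.n_bins, dtype=int)
        next_id = 0
        for p in np.unique(parent):
            idx = np.flatnonzero(parent == p)
            # split into `branching` contiguous chunks
            chunks = np.array_split(idx, spec.branching)
            for ch in chunks:
                child[ch] = next_id
                next_id += 1
        levels.append(child)
    # scatter: pairwise swap bins between sibling communities (size-preserving)
    if spec.scatter_fraction > 0:
        for lvl in range(1, spec.hierarchy_depth + 1):
            child = levels[lvl]
            parent = levels[lvl - 1]
            for p in np.unique(parent):
                idx = np.flatnonzero(parent == p)
                sibs = np.unique(child[idx])
                if sibs.size < 2:
                    continue
                n_swap = int(round(spec.scatter_fraction * idx.size / 2))
                for _ in range(n_swap):
                    a, b = rng.choice(idx, size=2, replace=False)
                    if child[a] != child[b]:
                        child[a], child[b] = child[b], child[a]
    if spec.reshuffle_q > 0:
        from .folding_model import reshuffle

        sub = int(rng.integers(0, 2**31 - 1))
        levels = [levels[0]] + reshuffle(levels[1:], spec.reshuffle_q, seed=sub)
    return levels


def _shared_levels(levels: list[np.ndarray]) -> np.ndarray:
    """Matrix counting, for each bin pair, the sub-root levels they share."""
    n = levels[0].shape[0]
    shared = np.zeros((n, n), dtype=int)
    for memb in levels[1:]:
        shared += memb[:, None] == memb[None, :]
    return shared


def synth_contact_matrix(
    spec: SyntheticSpec, hierarchy: list[np.ndarray] | None = None
) -> ContactMatrix:
    """Contact matrix with fractal-globule decay and planted block boosts.

    Expected count ``E_ij = base_count * |i-j|**(-alpha) * boost**shared(i,j)``
    where ``shared(i, j)`` counts the hierarchy levels (below the root) on
    which bins i and j are in the same community.  Counts are
    ``Poisson(E_ij)`` when noise is on, symmetric with zero diagonal.
    """
    if hierarchy is None:
        hierarchy = synth_hierarchy(spec)
    n = spec.n_bins
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(sep > 0, sep ** (-spec.decay_exponent), 0.0)
    expected = spec.base_count * decay * spec.boost ** _shared_levels(hierarchy)
    np.fill_diagonal(expected, 0.0)
    if spec.noise:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        upper = rng.poisson(np.triu(expected, k=1)).astype(float)
        counts = upper + upper.T
    else:
        counts = expected
    return ContactMatrix(counts, bin_size=spec.bin_size, chrom=spec.chrom)


def synth_chromatin_track(
    spec: SyntheticSpec,
    hierarchy: list[np.ndarray] | None = None,
    state_bias: dict[int, np.ndarray] | None = None,
    mean_peak_bins: float = 3.0,
    n_peaks: int | None = None,
) -> ChromatinTrack:
    """Chromatin-state peaks with per-branch state composition.

    Peaks are laid left to right with geometric lengths (mean
    ``mean_peak_bins`` bins, truncated to the chromosome); each peak's state
    is drawn from the weight vector of the deepest-level community owning its
    start bin (``state_bias``: community id -> length-15 weights; uniform
    where absent).
    """
    if hierarchy is None:
        hierarchy = synth_hierarchy(spec)
    deepest = hierarchy[-1]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    if n_peaks == 0:
        return ChromatinTrack(pd.DataFrame(columns=["chrom", "start", "end", "state"]))
    state_bias = state_bias or {}
    weights = {}
    for c in np.unique(deepest):
        w = np.asarray(state_bias.get(int(c), np.ones(15)), dtype=float)
        if w.shape != (15,) or w.sum() <= 0 or np.any(w < 0):
            raise ValueError(f"state weights for branch {c} not normalizable")
        weights[int(c)] = w / w.sum()
    total_bp = spec.n_bins * spec.bin_size
    rows = []
    pos = 0
    while pos < total_bp and (n_peaks is None or len(rows) < n_peaks):
        length = int(rng.geometric(1.0 / mean_peak_bins)) * spec.bin_size
        # sub-bin jitter keeps peak borders off bin borders
        length = max(spec.bin_size // 10, length - int(rng.integers(0, spec.bin_size // 2)))
        end = min(pos + length, total_bp)
        owner = int(deepest[min(pos // spec.bin_size, spec.n_bins - 1)])
        state = STATES[rng.choice(15, p=weights[owner])]
        rows.append((spec.chrom, pos, end, state))
        pos = end
    return ChromatinTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))
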