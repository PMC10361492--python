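# chromnest

Cross-scale community structure and nestedness of 3D chromosome contact
networks.

## The problem

Hi-C experiments measure contact counts between all pairs of DNA segments,
revealing 3D structures from megabase A/B compartments down to topologically
associated domains (TADs). A popular reading of these maps is a Russian-doll
hierarchy: small structures merge into ever larger ones and never split.
`chromnest` tests that picture quantitatively. It treats an intra-chromosomal
contact matrix as a weighted network, extracts 3D communities across a
continuum of scales, and measures how communities detected at different
scales nest into each other — perfectly, not at all, or no better than
chance.

It is a library for computational genomicists working with binned Hi-C-style
contact matrices (dense text, coordinate triples, or single-resolution
cooler containers), with a small CLI for end-to-end runs.

## The method

**Communities.** For a balanced contact matrix *A*, communities maximize the
generalized modularity

M = (1/2m) Σ_{i≠j} (A_ij − γ P_ij) δ(g_i, g_j),

where the null term follows the fractal-globule expectation
P_ij ∝ k_i k_j |i−j|^(−1), matching the empirical distance decay of chromatin
contacts. Sweeping the resolution parameter γ probes the full scale spectrum;
optimization is a Louvain-style greedy scheme on the dense modularity matrix.

**Domains and nestedness.** DNA stretches never split by any community
border across the sweep are the *irreducible domains*. Two communities found
at different resolutions share S of the chromosome's n domains; against a
uniform-random null the overlap is hypergeometric with mean μ = d_i d_j / n.
The nestedness score

N = (S − μ) / (Ω · min(d_i, d_j))

is normalized so that N = +1 at the maximum achievable overlap (full
nesting), N = −1 at the minimum (complete segregation) and N = 0 at random,
with an exact one-tailed p-value (threshold 0.025) separating significant
from random overlap.

**Folding model.** A minimal generative model agglomerates domains by
strongest mean interaction into a dendrogram (a perfect hierarchy, all
N = ±1), then reshuffles domain memberships within each organizational level
with probability Q. Q is fitted by minimizing the Kolmogorov–Smirnov
distance between model and observed nestedness distributions (±1 excluded).

**Chromatin states.** Communities are tested for enrichment in 15
ChromHMM-style chromatin states by an exact hypergeometric test
(Benjamini–Hochberg at FDR 0.05) and grouped into A (active promoters,
S1–S2), B (enhancers, S4–S7), C (transcribed, S9–S11) and D (heterochromatin,
S3, S12–S15) for group-wise nestedness and community-modularity comparisons.

A synthetic-data module generates contact matrices with power-law decay,
planted multi-level communities, Poisson noise and biased chromatin tracks,
so every stage is testable end to end without external data.

## Worked example

```python
import chromnest as cn

d_i, d_j, n = 12, 6, 18      # two communities sharing an 18-domain chromosome
cn.expected_overlap(d_i, d_j, n)      # 4.0
cn.nestedness_score(2, d_i, d_j, n)   # -0.5  (halfway to full segregation)
cn.nestedness_score(4, d_i, d_j, n)   #  0.0  (exactly the random expectation)
cn.nestedness_score(5, d_i, d_j, n)   #  0.5  (halfway to full nesting)
cn.nestedness_score(6, d_i, d_j, n)   #  1.0  (maximum achievable overlap)
```

Running `python examples/02_nestedness.py` prints these numbers and then a
full pipeline comparison:

```
planted reshuffling q=0.0: 904 community pairs, 100.0% at N=+-1, mean N=-0.56
planted reshuffling q=0.3: 340 community pairs, 61.5% at N=+-1, mean N=-0.31
```

With a perfect planted hierarchy (q=0) every cross-scale community pair is
fully nested or fully segregated; reshuffling 30% of memberships moves a
third of the pairs into intermediate nestedness, the signature of
semi-hierarchical folding. The other scripts under `examples/` demonstrate
the community sweep, the folding-model fit (recovering a planted Q), and
chromatin-group enrichment.

The CLI mirrors the stages:

```sh
chromnest synth out/ --n-bins 256 --seed 1
chromnest communities out/contacts.tsv results/ --gammas 0.3,0.6,0.9
chromnest run-all config.yaml --seed 1
```

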