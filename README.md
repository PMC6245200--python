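# h2embed

Hyperbolic embedding of complex networks: simulate popularity–similarity
networks, infer hidden hyperbolic coordinates of real networks with a fast
spectral method, a maximum-likelihood method or their hybrid, and judge the
result by how navigable the embedded network is.

## The problem

Many real networks — protein interactomes, webs of trust, airport networks —
are scale-free and strongly clustered, exactly the topology produced when
nodes live in the two-dimensional hyperbolic plane H² and connect
preferentially over short hyperbolic distances.  In the native disc model a
node sits at polar coordinates (r, θ): the radius encodes *popularity*
(older, better-connected nodes are central), the angle encodes *similarity*.
Recovering these latent coordinates from nothing but the adjacency makes the
network navigable (greedy forwarding by hyperbolic distance), exposes node
ages, and gives a geometric null model for its connectivity.

This package is aimed at network scientists and systems biologists who need
those coordinates at interactive speed: the spectral draft embeds a
10⁴-node network in seconds, and the hybrid refinement recovers most of the
accuracy of full maximum-likelihood inference at a fraction of its cost.

## Models and methods

**PS model** (`generate`).  Growing network of N nodes: node *t* is born at
radius r_t = 2 ln t with a uniform angle; older nodes fade outward,
r_s(t) = β·r_s + (1−β)·r_t with β = 1/(γ−1); node *t* links to m older
nodes with the Fermi–Dirac probability
p(x) = 1 / (1 + e^{(x − R_t)/2T}), where
x_st = r_s + r_t + 2 ln(θ_st/2) is the hyperbolic distance and R_t the
current disc radius.  γ ∈ [2,3] sets the degree exponent; the temperature
T ∈ [0,1) sets clustering (T = 0: connect to the m hyperbolically nearest —
maximal clustering).

**LaBNE** (`labne_embed`).  Laplacian-based network embedding: the two
eigenvectors with smallest nonzero eigenvalues of the generalized problem
L y = λ D y (L = D − A) minimise tr(YᵀLY) subject to YᵀDY = I; angles are
θ = atan2(y₂, y₁), re-spread uniformly on the circle in their inferred
order, and radii come from the degree ranking,
r_i = 2β ln i + 2(1−β) ln N.

**HyperMap** (`hypermap_embed`).  Maximum-likelihood replay of PS growth in
degree order: each re-born node receives the angle maximising either the
Bernoulli link likelihood ∏ p(x_ij)^{α_ij}(1−p(x_ij))^{1−α_ij} (low-degree
nodes, searched near a neighbour-based estimate) or a Gaussian
log-likelihood of observed common-neighbour counts against the model mean
μ = Σ_k p(x_ik)p(x_jk) (high-degree nodes, k_speedup = 10), on a candidate
grid of spacing 1/i radians.

**LaBNE+HM** (`labne_hm_embed`).  LaBNE drafts the geometry; HyperMap
refines each angle only inside a window w around the draft (w = 2πT,
2πT², or manual — e.g. π/6 for T = 0.3).  w → 0 behaves like LaBNE,
w → 2π like full HyperMap.

**Evaluation** (`routing_report`, `connection_probability_curve`,
`estimate_temperature`, `fit_power_law_exponent`).  Greedy routing success
and hop stretch over random source–target pairs; fraction of connected
pairs per distance bin; network temperature via T = 1 − c̄/c̄₀ against cold
PS replicas; maximum-likelihood degree-exponent fits.

## Worked example

```python
import math
from h2embed import (PSParams, WindowPolicy, generate, labne_embed,
                     labne_hm_embed, routing_report, estimate_temperature)

params = PSParams(N=500, m=5, gamma=2.5, T=0.6, seed=1)
gen = generate(params)                     # ground-truth coordinates included
net = gen.network()
print(f"network: N={net.N} L={net.L} mean degree={net.mean_degree:.2f}")

draft = labne_embed(net, gamma=2.5)
hybrid = labne_hm_embed(net, gamma=2.5, T=0.6,
                        policy=WindowPolicy("manual", math.pi / 4), seed=1)
for name, emb in [("LaBNE", draft), ("LaBNE+HM", hybrid)]:
    rep = routing_report(emb, net, n_pairs=1000, seed=2)
    print(f"{name:9s} success={100*rep.success_rate:.1f}%  "
          f"mean hop stretch={rep.mean_stretch:.3f}")

fit = estimate_temperature(net, gamma=2.5, n_replicas=5, seed=3)
print(f"estimated temperature: {fit.T_est:.2f} "
      f"(clustering {fit.cbar_real:.3f} vs cold replicas {fit.cbar_zero:.3f})")
```

prints

```
network: N=500 L=2485 mean degree=9.94
LaBNE     success=76.1%  mean hop stretch=1.109
LaBNE+HM  success=83.9%  mean hop stretch=1.138
estimated temperature: 0.62 (clustering 0.292 vs cold replicas 0.775)
```

A warm (T = 0.6), weakly clustered network embedded by the spectral draft
alone routes 76% of packets; the windowed likelihood refinement recovers
84%, close to the 86% achieved by the generator's true coordinates, and the
clustering-based estimator recovers the temperature the network was grown
at (0.62 vs 0.6).  Greedy paths are near-optimal in both cases (stretch
≈ 1.1).

The same operations are available from a shell:

```sh
h2embed generate --n 500 --m 5 --gamma 2.5 --temp 0.6 --seed 1 --out-prefix ps
h2embed embed --method labne-hm --edgelist ps.edgelist.tsv --gamma 2.5 \
              --temp 0.6 --window 45 --degrees --seed 1 --out coords.tsv
h2embed route --edgelist ps.edgelist.tsv --coords coords.tsv --pairs 1000 --seed 2
h2embed estimate-temp --edgelist ps.edgelist.tsv --gamma 2.5 --replicas 5 --seed 3
```

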