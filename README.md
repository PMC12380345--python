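# graip

Random graph generation with degree-distribution and graphlet-frequency
bounds derived from **probabilistic networks**.

Biological interaction data — protein–protein interaction networks in
particular — usually come with a confidence score per edge: an *uncertain
graph* 𝒢 = (V, E, P) with independent edge existence probabilities
P(e) ∈ (0, 1]. Such a network is not one graph but a distribution over
2^|E| *possible worlds*. Classical randomization schemes (edge swapping,
configuration models) need a single deterministic graph and silently
discard the uncertainty. This package generates deterministic random
graphs that are statistically consistent with the whole distribution: the
degree distribution **P** and the counts **C** of all 29 graphlets
(connected induced subgraphs) of orders 3–5 must land inside the envelope

  P_H ∈ [**E**_p − 2**s**_p, **E**_p + 2**s**_p]  and
  C_H ∈ [**E**_c − 2**s**_c, **E**_c + 2**s**_c],

where the means **E** and standard deviations **s** are estimated by
Monte-Carlo sampling of S possible worlds (largest connected component of
each). It is intended for network biologists and method developers who
need null ensembles, surrogate data or benchmarking graphs that respect
both the local wiring patterns and the uncertainty of a measured network.

## What is inside

- **Incremental generator** (`graip.generator.generate`): grows a graph
  from a small preferential-attachment seed by single node/edge moves.
  Moves are gated by logistic functions of the standardized deviation of
  the current order and (scaled) size from the target, and accepted when
  they lower a two-part cost — the mean relative deviation of the
  reversed-cumulative binned degree distribution, plus a logarithmic
  penalty for every graphlet count outside its band — or unconditionally
  after `max_rej` consecutive rejections. Graphlet counts are maintained
  *incrementally*: an edge edit only touches instances through that edge,
  so only connected sets containing both endpoints are re-classified via
  a precomputed bit-string lookup table.
- **SwapCon baseline** (`graip.swapcon`): degree sequence drawn from the
  sampled expected degree distribution, configuration-model construction,
  then degree-preserving double-edge swaps under simulated annealing
  toward the expected graphlet counts.
- **Possible-world machinery** (`graip.worlds`): world sampling, exact
  world probabilities, closed-form degree moments
  E[k_v] = Σ P(e), Var[k_v] = Σ P(e)(1 − P(e)) over incident edges.
- **Degree-histogram binning** (`graip.stats`): high-degree nodes spread
  over many degrees across samples, so per-degree means drop below one
  node and would be unreachable by any single graph; binning from the
  high-degree side groups degrees until each bin holds mean weight ≥ 1,
  keeps unobserved ranges as zero-weight bins, and moves peak tails
  (degrees seen in < 1% of samples) into them.
- **Evaluation** (`graip.evaluation`): unbiased squared maximum mean
  discrepancy with a Gaussian kernel between generated and sampled
  ensembles (degree or graphlet statistic vectors), and 5th–95th
  percentile spread ratios of diameter and mean local clustering as a
  randomness proxy.
- **Synthetic fixtures** (`graip.graphs`): uncertain Erdős–Rényi,
  Barabási–Albert and star graphs with probabilities uniform on (0, 1],
  so every experiment here is reproducible without downloads.

## Worked example

```python
import numpy as np
from graip import make_uncertain_er, sample_statistics, generate, GeneratorParams
from graip.counting import count_all
from graip.generator import within_bounds, _binned_fractions

target = make_uncertain_er(50, 4, rng_seed=7)       # uncertain ER target
rng = np.random.default_rng(0)
stats = sample_statistics(target, 500, 4, rng)      # S=500 worlds, orders <= 4
print(f"target envelope: E_n={stats.E_n:.2f}  E_m={stats.E_m:.2f}  "
      f"cc_bar={stats.cc_bar:.3f}  bins={stats.bins.n_bins}")
print("E_c =", np.round(stats.E_c, 1))
print("s_c =", np.round(stats.s_c, 1))
H = generate(stats, GeneratorParams(n_g=4), rng=rng)
C = count_all(H, 4)
print(f"generated: n={H.number_of_nodes()}  m={H.number_of_edges()}")
print("C_H =", C)
print("within bounds:", within_bounds(_binned_fractions(H, stats), C, stats))
```

This prints (numbers from an actual run):

```
target envelope: E_n=41.38  E_m=49.58  cc_bar=0.018  bins=5
E_c = [ 91.6   0.5  44.3 161.6   2.4   1.8   0.    0. ]
s_c = [16.7  0.6 14.5 43.9  2.8  1.4  0.2  0. ]
generated: n=21  m=26
C_H = [ 64   0  70 114   0   0   0   0]
within bounds: True
```

Reading it: the target's sampled worlds keep on average 41.4 nodes and
49.6 edges in their largest component; the eight entries of `E_c`/`s_c`
are the mean/stdev counts of the graphlet types M1–M8 (open triplet,
triangle, then the six 4-node types). The generated graph's counts `C_H`
all lie inside `E_c ± 2 s_c` and its binned degree distribution inside
`E_p ± 2 s_p`, so generation stopped. Note the envelope of a uniformly
uncertain target is wide — graphs of quite different order can satisfy
it, which is exactly the variability the possible worlds themselves show.

The same workflow is available from the shell:

```sh
graip fixtures --model er -n 50 --mean-degree 4 --seed 7 --output target.tsv
graip sample-stats --input target.tsv --samples 10000 --max-graphlet-order 4 \
      --seed 0 --output stats.json
graip generate --stats-cache stats.json --max-graphlet-order 4 --seed 1 \
      --output graph.tsv
graip pipeline --config run.yaml   # stats + ensemble + MMD/spread report
```

## Layout

```
src/graip/graphs.py      uncertain-graph model, I/O, synthetic fixtures
src/graip/worlds.py      possible-world sampling and degree moments
src/graip/catalog.py     29 graphlet types, bit-string lookup tables
src/graip/counting.py    full counts, clustering, incremental deltas
src/graip/stats.py       sampled target envelope, degree binning
src/graip/generator.py   the incremental generator
src/graip/swapcon.py     configuration-model + annealing baseline
src/graip/evaluation.py  MMD and spread-ratio metrics
src/graip/cli.py         click subcommands and the pipeline
```

See `docs/methods.md` for the model, parameter choices and limitations.
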