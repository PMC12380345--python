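"""Sampling-based statistical envelope of a probabilistic target network.

The generator does not chase point targets: it keeps the degree
distribution and graphlet counts of the growing graph inside the band
mean +/- 2 stdev estimated from S Monte-Carlo possible worlds of the
uncertain target (largest connected component of each world).

Degree histograms are *binned* before use.  A single high-degree node of
the backbone spreads over many degrees across samples, so each per-degree
mean falls below one node and no generated graph could ever match it;
binning from the high-degree side groups degrees until each bin carries a
total mean weight of at least one.  Runs of unobserved degrees become
dedicated zero-weight bins, and degrees occurring in fewer than 1% of
samples are treated as peak tails and moved into adjacent zero bins so
that bin widths do not grow with the number of samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .counting import count_all
from .graphs import UncertainGraph
from .worlds import largest_connected_component, sample_world

__all__ = [
    "BinnedDegreeSpec",
    "TargetStatistics",
    "wide_bin_stdev",
    "bin_degrees",
    "binned_counts",
    "sample_statistics",
]

#: a degree is a peak tail if its mean per-sample occurrence is below this
TAIL_THRESHOLD = 0.01


def wide_bin_stdev(weight: float) -> float:
    """Stdev assigned to a multi-degree bin of the given mean weight.

    The number of nodes of a generated graph falling in a bin is an
    integer while the mean weight usually is not, so the stdev is the
    minimal s for which [weight - 2s, weight + 2s] contains both
    floor(weight) and ceil(weight):

        s = max(weight - floor(weight), ceil(weight) - weight) / 2
    """
    if weight < 0:
        raise ValueError("weight must be nonnegative")
    return max(weight - math.floor(weight), math.ceil(weight) - weight) / 2.0


@dataclass
class BinnedDegreeSpec:
    """Half-open degree bins [edges[i], edges[i+1]) with mean weights.

    ``zero_bins[i]`` flags bins created for runs of unobserved degrees
    (they may carry a small tail weight after the tail adjustment).
    """

    bin_edges: np.ndarray   # ascending ints, length B + 1
    weights: np.ndarray     # length B
    s_binned: np.ndarray    # per-bin stdev on the weight
    zero_bins: np.ndarray   # length B, bool

    @property
    def n_bins(self) -> int:
        return len(self.weights)

    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def bin_of(self, degree: int) -> int:
        """Bin index of a degree; out-of-range degrees clamp to the
        nearest boundary bin so they always register (and, carrying weight
        the target never put there, push the graph out of bounds)."""
        idx = int(np.searchsorted(self.bin_edges, degree, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)


def bin_degrees(
    E_N: np.ndarray, S: int, s_N: np.ndarray | None = None
) -> BinnedDegreeSpec:
    """Bin a mean degree histogram (index = degree, degree 0 ignored).

    Sweeps from the highest observed degree downwards, closing a bin when
    its accumulated weight reaches one (so isolated high-degree peaks of
    total mean one land in a single bin), when a run of zero-mean degrees
    ends, or at degree one.  Afterwards, tail degrees (mean occurrence
    below 1% per sample) at the boundary of a nonzero bin are moved into
    an adjacent zero bin, weight included.

    Per-bin stdevs: width-one bins keep the sampled per-degree stdev
    (``s_N``); wider bins use :func:`wide_bin_stdev`, as the sampled value
    no longer applies once degree uncertainty is absorbed by bin width.
    """
    E_N = np.asarray(E_N, dtype=float)
    if E_N.ndim != 1 or np.any(E_N < 0):
        raise ValueError("E_N must be a nonnegative 1-d histogram")
    if not np.any(E_N[1:] > 0):
        raise ValueError("degree histogram has no mass at degree >= 1")

    # accumulate in raw-count scale (integers across S samples), so the
    # weight-one closing threshold is exact instead of drifting in floats
    N = np.round(E_N * S)
    L = len(E_N)
    desc_edges = [L]
    desc_weights: list[float] = []
    zero_flags: list[bool] = []
    bin_edge = L
    zero_bin = False
    w = 0.0
    while bin_edge > 1:
        bin_edge -= 1
        w += N[bin_edge]
        if (
            bin_edge == 1
            or w >= S - 0.5
            or (zero_bin and N[bin_edge - 1] != 0)
        ):
            desc_edges.append(bin_edge)
            desc_weights.append(w / S)
            zero_flags.append(w == 0.0)
            w = 0.0
            zero_bin = N[bin_edge - 1] == 0

    edges = list(reversed(desc_edges))
    weights = list(reversed(desc_weights))
    zeros = list(reversed(zero_flags))

    _move_tails(edges, weights, zeros, E_N)

    edges_arr = np.asarray(edges, dtype=int)
    weights_arr = np.asarray(weights, dtype=float)
    zeros_arr = np.asarray(zeros, dtype=bool)
    s = np.zeros(len(weights_arr))
    widths = np.diff(edges_arr)
    for i, wt in enumerate(weights_arr):
        if widths[i] == 1 and s_N is not None:
            k = edges_arr[i]
            s[i] = s_N[k] if k < len(s_N) else 0.0
        elif widths[i] == 1:
            s[i] = 0.0
        else:
            s[i] = wide_bin_stdev(wt)
    return BinnedDegreeSpec(edges_arr, weights_arr, s, zeros_arr)


def _move_tails(
    edges: list[int], weights: list[float], zeros: list[bool], E_N: np.ndarray
) -> None:
    """Shift rare boundary degrees of nonzero bins into adjacent zero bins."""
    n = len(weights)
    for i in range(n):
        if zeros[i]:
            continue
        # low side: zero bin below
        if i > 0 and zeros[i - 1]:
            while edges[i + 1] - edges[i] > 1 and 0 < E_N[edges[i]] < TAIL_THRESHOLD:
                weights[i] -= E_N[edges[i]]
                weights[i - 1] += E_N[edges[i]]
                edges[i] += 1
        # high side: zero bin above
        if i < n - 1 and zeros[i + 1]:
            while edges[i + 1] - edges[i] > 1 and 0 < E_N[edges[i + 1] - 1] < TAIL_THRESHOLD:
                weights[i] -= E_N[edges[i + 1] - 1]
                weights[i + 1] += E_N[edges[i + 1] - 1]
                edges[i + 1] -= 1


def binned_counts(degrees: Iterable[int], spec: BinnedDegreeSpec) -> np.ndarray:
    """Node counts of a graph per target bin (out-of-range degrees clamp)."""
    counts = np.zeros(spec.n_bins)
    for k in degrees:
        counts[spec.bin_of(k)] += 1
    return counts


@dataclass
class TargetStatistics:
    """Means and stdevs of the target's sampled properties.

    All quantities refer to the largest connected component of each of the
    S possible worlds.  ``E_p``/``s_p`` are the binned degree-distribution
    envelope (weights normalized by the mean order ``E_n``), ``E_c``/``s_c``
    the graphlet-count envelope in catalog order, and ``cc_bar`` the
    average global clustering coefficient derived from the mean counts of
    the open-triplet and triangle graphlets.
    """

    S: int
    n_g: int
    E_n: float
    s_n: float
    E_m: float
    s_m: float
    E_N: np.ndarray
    s_N: np.ndarray
    bins: BinnedDegreeSpec
    E_p: np.ndarray
    s_p: np.ndarray
    E_c: np.ndarray
    s_c: np.ndarray
    cc_bar: float

    # -- serialization (JSON, so the expensive sampling step is cacheable) --

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "n_g": self.n_g,
            "E_n": self.E_n,
            "s_n": self.s_n,
            "E_m": self.E_m,
            "s_m": self.s_m,
            "E_N": self.E_N.tolist(),
            "s_N": self.s_N.tolist(),
            "bin_edges": self.bins.bin_edges.tolist(),
            "weights": self.bins.weights.tolist(),
            "s_binned": self.bins.s_binned.tolist(),
            "zero_bins": self.bins.zero_bins.astype(int).tolist(),
            "E_p": self.E_p.tolist(),
            "s_p": self.s_p.tolist(),
            "E_c": self.E_c.tolist(),
            "s_c": self.s_c.tolist(),
            "cc_bar": self.cc_bar,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetStatistics":
        bins = BinnedDegreeSpec(
            np.asarray(d["bin_edges"], dtype=int),
            np.asarray(d["weights"], dtype=float),
            np.asarray(d["s_binned"], dtype=float),
            np.asarray(d["zero_bins"], dtype=bool),
        )
        return cls(
            S=d["S"],
            n_g=d["n_g"],
            E_n=d["E_n"],
            s_n=d["s_n"],
            E_m=d["E_m"],
            s_m=d["s_m"],
            E_N=np.asarray(d["E_N"], dtype=float),
            s_N=np.asarray(d["s_N"], dtype=float),
            bins=bins,
            E_p=np.asarray(d["E_p"], dtype=float),
            s_p=np.asarray(d["s_p"], dtype=float),
            E_c=np.asarray(d["E_c"], dtype=float),
            s_c=np.asarray(d["s_c"], dtype=float),
            cc_bar=d["cc_bar"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TargetStatistics":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sample_statistics(
    g: UncertainGraph, S: int, n_g: int, rng: np.random.Generator
) -> TargetStatistics:
    """Estimate the target envelope from S sampled possible worlds.

    For each world the largest connected component is taken and its order,
    size, degree histogram and graphlet count vector recorded; means and
    (population) stdevs are computed per quantity, degrees are binned, and
    the binned degree-distribution envelope is derived as weights / E_n.
    """
    if S < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    ns = np.empty(S)
    ms = np.empty(S)
    count_rows = []
    hist_sum = np.zeros(1)
    hist_sq = np.zeros(1)
    for i in range(S):
        world = sample_world(g, rng)
        lcc = largest_connected_component(world)
        ns[i] = lcc.number_of_nodes()
        ms[i] = lcc.number_of_edges()
        degs = np.fromiter((d for _, d in lcc.degree), dtype=int, count=int(ns[i]))
        hist = np.bincount(degs)
        if len(hist) > len(hist_sum):
            hist_sum = np.pad(hist_sum, (0, len(hist) - len(hist_sum)))
            hist_sq = np.pad(hist_sq, (0, len(hist) - len(hist_sq)))
        hist_sum[: len(hist)] += hist
        hist_sq[: len(hist)] += hist.astype(float) ** 2
        count_rows.append(count_all(lcc, n_g))

    counts = np.asarray(count_rows, dtype=float)
    E_N = hist_sum / S
    s_N = np.sqrt(np.maximum(hist_sq / S - E_N**2, 0.0))
    E_c = counts.mean(axis=0)
    s_c = counts.std(axis=0)  # population formula, ddof=0
    E_n = float(ns.mean())
    bins = bin_degrees(E_N, S, s_N)
    E_p = bins.weights / E_n
    s_p = bins.s_binned / E_n
    # average global clustering from the mean open-triplet / triangle counts
    denom = E_c[0] + 3.0 * E_c[1]
    cc_bar = 0.0 if denom == 0.0 else 3.0 * E_c[1] / denom
    return TargetStatistics(
        S=S,
        n_g=n_g,
        E_n=E_n,
        s_n=float(ns.std()),
        E_m=float(ms.mean()),
        s_m=float(ms.std()),
        E_N=E_N,
        s_N=s_N,
        bins=bins,
        E_p=E_p,
        s_p=s_p,
        E_c=E_c,
        s_c=s_c,
        cc_bar=cc_bar,
    )
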