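"""Ensemble comparison metrics: squared MMD and randomness spread ratios.

Generated graphs are compared to sampled possible worlds as *ensembles*:
the squared maximum mean discrepancy (with a Gaussian kernel) between the
two sets of per-graph statistic vectors measures quality, and the ratio of
5th-95th percentile spreads of properties not directly controlled by the
generator (diameter, mean local clustering) measures randomness.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .counting import clustering_local, count_all
from .worlds import largest_connected_component

__all__ = [
    "gaussian_kernel",
    "mmd_squared",
    "median_heuristic_sigma",
    "graph_statistic_vectors",
    "spread_ratio",
    "mmd_batched",
]


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||x - y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("statistic vectors must have equal length")
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=-1)


def mmd_squared(
    X: Sequence[np.ndarray], Y: Sequence[np.ndarray], sigma: float
) -> float:
    """Unbiased squared-MMD estimator between two sets of vectors.

    Diagonal terms are excluded from the within-set averages, so the
    estimate can be slightly negative; it is near zero when both sets come
    from the same distribution.
    """
    A = np.asarray(X, dtype=float)
    B = np.asarray(Y, dtype=float)
    na, nb = len(A), len(B)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 vectors per side")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    kaa = np.exp(-_sq_dists(A, A) / (2 * sigma**2))
    kbb = np.exp(-_sq_dists(B, B) / (2 * sigma**2))
    kab = np.exp(-_sq_dists(A, B) / (2 * sigma**2))
    term_a = (kaa.sum() - np.trace(kaa)) / (na * (na - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (nb * (nb - 1))
    term_ab = 2.0 * kab.sum() / (na * nb)
    return float(term_a + term_b - term_ab)


def median_heuristic_sigma(
    X: Sequence[np.ndarray], Y: Sequence[np.ndarray]
) -> float:
    """Median pairwise distance over the pooled vectors; 1.0 if that
    median is zero (all vectors identical)."""
    P = np.asarray(list(X) + list(Y), dtype=float)
    d = np.sqrt(_sq_dists(P, P))
    med = float(np.median(d[np.triu_indices(len(P), k=1)]))
    return med if med > 0 else 1.0


def graph_statistic_vectors(
    graphs: Iterable[nx.Graph],
    kind: str,
    n_g: int = 4,
    normalize: bool = False,
) -> list[np.ndarray]:
    """Per-graph statistic vectors for the MMD.

    ``kind="degree"``: normalized degree histograms, zero-padded to the
    ensemble-wide maximum degree.  ``kind="graphlets"``: graphlet count
    vectors up to order ``n_g``; raw counts by default (no normalization
    convention is imposed), fractions of the total when ``normalize``.
    """
    graphs = list(graphs)
    if kind == "degree":
        hists = []
        for g in graphs:
            degs = [d for _, d in g.degree]
            h = np.bincount(degs) if degs else np.zeros(1, dtype=int)
            n = g.number_of_nodes()
            hists.append(h / n if n else h.astype(float))
        width = max(len(h) for h in hists)
        return [np.pad(h, (0, width - len(h))) for h in hists]
    if kind == "graphlets":
        out = []
        for g in graphs:
            c = count_all(g, n_g).astype(float)
            if normalize and c.sum() > 0:
                c = c / c.sum()
            out.append(c)
        return out
    raise ValueError(f"unknown statistic kind {kind!r}")


def _property_values(graphs: Iterable[nx.Graph], prop: str) -> np.ndarray:
    vals = []
    for g in graphs:
        if prop == "diameter":
            lcc = largest_connected_component(g)
            vals.append(nx.diameter(lcc) if lcc.number_of_nodes() > 1 else 0)
        elif prop == "mean_local_cc":
            n = g.number_of_nodes()
            vals.append(
                sum(clustering_local(g, v) for v in g.nodes) / n if n else 0.0
            )
        else:
            raise ValueError(f"unknown property {prop!r}")
    return np.asarray(vals, dtype=float)


def spread_ratio(
    generated: Sequence[nx.Graph],
    sampled: Sequence[nx.Graph],
    prop: str,
) -> float | None:
    """Ratio of 5th-95th percentile spreads, generated over sampled.

    Percentiles use linear interpolation.  Above one means the generated
    ensemble is more diverse than the sampled one on this property.
    Returns ``None`` (undefined) when the sampled spread is zero.
    """
    if len(generated) < 20 or len(sampled) < 20:
        raise ValueError("need at least 20 graphs per ensemble")
    gen = _property_values(generated, prop)
    ref = _property_values(sampled, prop)
    spread_gen = np.percentile(gen, 95) - np.percentile(gen, 5)
    spread_ref = np.percentile(ref, 95) - np.percentile(ref, 5)
    if spread_ref == 0:
        return None
    return float(spread_gen / spread_ref)


def mmd_batched(
    generated: Sequence[nx.Graph],
    sampled: Sequence[nx.Graph],
    kind: str,
    n_g: int = 4,
    batches: int = 10,
    batch_size: int = 100,
    sigma: float | None = None,
    normalize: bool = False,
) -> float:
    """Mean squared MMD over batch-wise comparisons.

    Mirrors the batch protocol used for ensemble scoring: the generated
    graphs are split into ``batches`` batches of ``batch_size`` and each
    is compared against an equally sized slice of sampled graphs; the
    reported score is the average.  Vectors of both ensembles are padded
    to a common length; the bandwidth defaults to the median heuristic
    over the pooled vectors.
    """
    vec_all = graph_statistic_vectors(
        list(generated) + list(sampled), kind, n_g=n_g, normalize=normalize
    )
    width = max(len(v) for v in vec_all)
    vec_all = [np.pad(v, (0, width - len(v))) for v in vec_all]
    gen_v = vec_all[: len(generated)]
    ref_v = vec_all[len(generated):]
    if sigma is None:
        sigma = median_heuristic_sigma(gen_v, ref_v)
    scores = []
    for b in range(batches):
        gsl = gen_v[b * batch_size: (b + 1) * batch_size]
        rsl = ref_v[b * batch_size: (b + 1) * batch_size]
        if len(gsl) < 2 or len(rsl) < 2:
            break
        scores.append(mmd_squared(gsl, rsl, sigma))
    if not scores:
        raise ValueError("not enough graphs for a single batch")
    return float(np.mean(scores))
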