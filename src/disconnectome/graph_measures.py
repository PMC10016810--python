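"""Graph-connectivity measures on (virtually lesioned) connectomes.

The measure battery follows the standard network-neuroscience repertoire:
eleven measures computed on binary graphs obtained by density-matched
thresholding, and seven computed directly on the weighted matrix.  Node-level
measures are summarized over nodes by mean and/or median, giving one global
value per measure; per-patient values are finally averaged across the healthy
connectomes that were virtually lesioned with the patient's mask.

Conventions for degenerate inputs (documented and tested):

* clustering and flow coefficients are 0 for nodes of degree < 2;
* participation coefficient is 0 for isolated nodes;
* an empty graph has density 0, all node summaries 0 and modularity 0;
* quasi-idempotence is undefined (``nan``) when node strengths have zero
  variance.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import shortest_path

from .virtual_lesion import Connectome

__all__ = [
    "BinaryGraph",
    "BINARY_MEASURES",
    "WEIGHTED_MEASURES",
    "MEASURE_NAMES",
    "weighted_density",
    "binarize_to_density",
    "binary_measure_suite",
    "weighted_measure_suite",
    "connectome_measures",
    "patient_measure_average",
]

#: number of Louvain restarts; best-modularity partition is kept
LOUVAIN_RESTARTS = 10

BINARY_MEASURES = [
    "density",
    "degree_median",
    "clustering_coef_mean",
    "clustering_coef_median",
    "flow_coef_mean",
    "transitivity",
    "modularity",
    "eigenvector_centrality_mean",
    "eigenvector_centrality_median",
    "betweenness_centrality_mean",
    "betweenness_centrality_median",
]

WEIGHTED_MEASURES = [
    "algebraic_connectivity",
    "eigenvector_centrality_w_mean",
    "eigenvector_centrality_w_median",
    "modularity_w",
    "global_efficiency_w",
    "participation_coef_w_mean",
    "quasi_idempotence",
]

MEASURE_NAMES = BINARY_MEASURES + WEIGHTED_MEASURES


class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal."""

    def __init__(self, adjacency: np.ndarray, threshold_used: float = np.nan):
        adj = np.asarray(adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isin(adj, (0, 1))):
            raise ValueError("entries must be 0 or 1")
        self.adjacency = adj.astype(np.int8)
        self.threshold_used = float(threshold_used)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def weighted_density(c: Connectome) -> float:
    """Max-normalized mean edge weight.

    ``sum_{i<j} (w_ij / w_max) / (N(N-1)/2)``; reduces to the binary edge
    density on a 0/1 matrix and is 0 for an all-zero matrix by convention.
    """
    w = c.weights
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0 or n < 2:
        return 0.0
    iu = np.triu_indices(n, 1)
    return float((w[iu] / wmax).sum() / (n * (n - 1) / 2))


def binarize_to_density(c: Connectome, target_density: float) -> BinaryGraph:
    """Threshold the weighted matrix to a target edge density.

    Keeps the ``k = round(target * N(N-1)/2)`` largest-weight region pairs,
    breaking ties at the cutoff by lexicographic ``(i, j)`` order.
    Zero-weight pairs never become edges, even if ``k`` demands it.
    """
    if not 0.0 <= target_density <= 1.0:
        raise ValueError(f"target_density must be in [0, 1], got {target_density}")
    w = c.weights
    n = w.shape[0]
    m = n * (n - 1) // 2
    k = int(round(target_density * m))
    iu = np.triu_indices(n, 1)
    vals = w[iu]
    # sort by descending weight, lexicographic (i, j) among ties
    order = np.lexsort((iu[1], iu[0], -vals))
    keep = order[:k]
    keep = keep[vals[keep] > 0]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj += adj.T
    thr = float(vals[keep].min()) if len(keep) else np.inf
    return BinaryGraph(adj, threshold_used=thr)


# ---------------------------------------------------------------------------
# helpers


def _eigenvector_centrality(w: np.ndarray) -> np.ndarray:
    """Principal eigenvector of a symmetric nonnegative matrix, unit norm,
    nonnegative sign convention (zero matrix -> zero vector).

    When the top eigenvalue is degenerate (e.g. identical disconnected
    components), the vector of ones is projected onto the top eigenspace,
    which yields a nonnegative representative.
    """
    if w.max() == 0:
        return np.zeros(w.shape[0])
    evals, evecs = np.linalg.eigh(w)
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    if v.min() < -1e-9:
        top = evals > evals[-1] - 1e-9 * max(abs(evals[-1]), 1.0)
        basis = evecs[:, top]
        v = basis @ (basis.T @ np.ones(w.shape[0]))
        nrm = np.linalg.norm(v)
        if nrm == 0:  # ones orthogonal to top space; keep eigh vector
            v = np.abs(evecs[:, -1])
        else:
            v = v / nrm
    return np.clip(v, 0.0, None)


def _best_louvain(G: nx.Graph, seed: int, resolution: float = 1.0):
    """Best-of-LOUVAIN_RESTARTS Louvain partition by modularity."""
    if G.number_of_edges() == 0:
        return [{n} for n in G.nodes], 0.0
    best_q, best_part = -np.inf, None
    for r in range(LOUVAIN_RESTARTS):
        part = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=int(seed) + r
        )
        q = nx.community.modularity(G, part, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_part = q, part
    return best_part, float(best_q)


def _median(x: np.ndarray) -> float:
    return float(np.median(x)) if len(x) else 0.0


def global_efficiency_weighted(c: Connectome) -> float:
    """Mean over ordered node pairs of ``1 / d(i, j)`` with shortest-path
    distances on edge lengths ``1 / (w_ij / w_max)``; unreachable pairs
    contribute 0."""
    w = c.weights
    n = w.shape[0]
    if n < 2:
        return 0.0
    wmax = w.max()
    wn = w / wmax if wmax > 0 else w
    with np.errstate(divide="ignore"):
        lengths = np.where(wn > 0, 1.0 / wn, np.inf)
    d = shortest_path(lengths, method="D", directed=False)
    np.fill_diagonal(d, np.inf)
    inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# measure suites


def binary_measure_suite(b: BinaryGraph, seed: int = 0) -> dict[str, float]:
    """Eleven binary-graph measures.

    Degrees, Watts-Strogatz clustering, flow coefficient (fraction of a
    node's neighbour pairs linked through it but not directly), transitivity,
    Newman modularity of the best seeded Louvain partition, eigenvector
    centrality and unnormalized shortest-path betweenness.
    """
    a = b.adjacency.astype(float)
    n = b.n_nodes
    out: dict[str, float] = {}
    deg = a.sum(axis=1)
    out["density"] = float(a.sum() / (n * (n - 1))) if n > 1 else 0.0
    out["degree_median"] = _median(deg)

    a3_diag = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * triangles per node
    pairs = deg * (deg - 1)  # 2 * (k choose 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        clust = np.where(pairs > 0, a3_diag / pairs, 0.0)
        flow = np.where(pairs > 0, 1.0 - a3_diag / pairs, 0.0)
    out["clustering_coef_mean"] = float(clust.mean()) if n else 0.0
    out["clustering_coef_median"] = _median(clust)
    out["flow_coef_mean"] = float(flow.mean()) if n else 0.0

    triples = pairs.sum()
    out["transitivity"] = float(a3_diag.sum() / triples) if triples > 0 else 0.0

    G = nx.from_numpy_array(b.adjacency)
    _, q = _best_louvain(G, seed)
    out["modularity"] = q

    ec = _eigenvector_centrality(a)
    out["eigenvector_centrality_mean"] = float(ec.mean()) if n else 0.0
    out["eigenvector_centrality_median"] = _median(ec)

    bc = np.array(
        [v for _, v in sorted(nx.betweenness_centrality(G, normalized=False).items())]
    )
    out["betweenness_centrality_mean"] = float(bc.mean()) if n else 0.0
    out["betweenness_centrality_median"] = _median(bc)
    return out


def weighted_measure_suite(
    c: Connectome, gamma: float = 1.0, seed: int = 0
) -> dict[str, float]:
    """Seven weighted-graph measures.

    Algebraic connectivity is the second-smallest eigenvalue of the raw
    weighted Laplacian ``D - W`` (so it scales with the weights); all other
    measures are computed on the max-normalized matrix and are invariant to
    a global rescaling of the weights.  Global efficiency uses edge lengths
    ``1 / (w_ij / w_max)`` with unreachable pairs contributing 0.
    Quasi-idempotence is the Pearson correlation between node strengths of
    the normalized matrix and of its square (``nan`` when degenerate).
    """
    w = c.weights
    n = w.shape[0]
    out: dict[str, float] = {}

    lap = np.diag(w.sum(axis=1)) - w
    evals = np.linalg.eigvalsh(lap)
    out["algebraic_connectivity"] = float(max(evals[1], 0.0)) if n > 1 else 0.0

    wmax = w.max()
    wn = w / wmax if wmax > 0 else w

    ec = _eigenvector_centrality(wn)
    out["eigenvector_centrality_w_mean"] = float(ec.mean()) if n else 0.0
    out["eigenvector_centrality_w_median"] = _median(ec)

    G = nx.from_numpy_array(wn)
    part, q = _best_louvain(G, seed, resolution=gamma)
    out["modularity_w"] = q

    out["global_efficiency_w"] = global_efficiency_weighted(c)

    strength = wn.sum(axis=1)
    module_of = np.empty(n, dtype=int)
    for m_idx, comm in enumerate(part):
        for node in comm:
            module_of[node] = m_idx
    s_im = np.zeros((n, len(part)))
    for m_idx in range(len(part)):
        s_im[:, m_idx] = wn[:, module_of == m_idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(strength[:, None] > 0, s_im / strength[:, None], 0.0)
    participation = np.where(strength > 0, 1.0 - (frac**2).sum(axis=1), 0.0)
    out["participation_coef_w_mean"] = float(participation.mean()) if n else 0.0

    s2 = (wn @ wn).sum(axis=1)
    if np.std(strength) == 0 or np.std(s2) == 0:
        out["quasi_idempotence"] = np.nan
    else:
        out["quasi_idempotence"] = float(np.corrcoef(strength, s2)[0, 1])
    return out


def connectome_measures(c: Connectome, gamma: float = 1.0, seed: int = 0) -> dict[str, float]:
    """Full measure vector for one connectome: the binary suite on the
    density-matched binarization plus the weighted suite."""
    bg = binarize_to_density(c, weighted_density(c))
    out = binary_measure_suite(bg, seed=seed)
    out.update(weighted_measure_suite(c, gamma=gamma, seed=seed))
    return out


def patient_measure_average(
    per_connectome: list[dict[str, float]],
) -> tuple[dict[str, float], dict[str, int]]:
    """Mean of each measure across virtually lesioned connectomes.

    Missing (``nan``) values are excluded pairwise; the second return value
    reports how many connectomes contributed to each measure.
    """
    if not per_connectome:
        raise ValueError("need at least one measure vector")
    keys = list(per_connectome[0])
    for mv in per_connectome:
        if list(mv) != keys:
            raise ValueError("measure vectors must share identical keys")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for k in keys:
        vals = np.array([mv[k] for mv in per_connectome], dtype=float)
        ok = ~np.isnan(vals)
        counts[k] = int(ok.sum())
        means[k] = float(vals[ok].mean()) if counts[k] else np.nan
    return means, counts
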