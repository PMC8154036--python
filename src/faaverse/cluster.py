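"""Cluster-based permutation testing over arbitrary adjacency graphs.

The multiple-comparison procedure at the heart of the frontal-asymmetry
analyses, implemented from scratch so it works on any search space: channel
sets, channel x frequency lattices, pair spaces, or source-vertex meshes.

Algorithm: a pointwise statistic (Welch t for group contrasts, OLS slope t
for linear contrasts, regression-adjusted when confounds are controlled) is
computed at every node; nodes whose statistic exceeds the two-sided critical
value at the entry alpha are grouped into connected components separately for
positive and negative signs; each cluster is summarized by its mass (sum of
member statistics).  Condition labels (or predictor values) are then permuted
between subjects; each permutation contributes the highest positive and the
lowest negative cluster mass to tail-specific null distributions, against
which the observed cluster masses are compared.  When the number of distinct
relabelings is no larger than ``n_perm`` the full enumeration is used and the
p-values are exact.

Tail handling: by default each cluster is compared only to its own tail's
null and the tail p is reported as-is (the procedure as commonly described).
``two_sided_p=True`` doubles the tail p (capped at 1) for strict two-sided
error control; without doubling, the chance of *some* cluster reaching
p < alpha under the null is close to 2 * alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterResult",
    "build_channel_adjacency",
    "grid_adjacency",
    "pair_graph",
    "product_adjacency",
    "find_clusters",
    "cluster_permutation_test",
    "cluster_asymmetry_test",
    "node_sides_product",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbour structure over the search-space nodes."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    node_ids: tuple[str, ...] | None = None
    _neighbors: tuple[tuple[int, ...], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        nbrs: list[set[int]] = [set() for _ in range(self.n_nodes)]
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError("edge endpoint outside node range")
            canon.add((min(i, j), max(i, j)))
            nbrs[i].add(j)
            nbrs[j].add(i)
        object.__setattr__(self, "edges", tuple(sorted(canon)))
        object.__setattr__(
            self, "_neighbors", tuple(tuple(sorted(s)) for s in nbrs)
        )

    @property
    def neighbors(self) -> tuple[tuple[int, ...], ...]:
        return self._neighbors


@dataclass(frozen=True)
class Cluster:
    nodes: tuple[int, ...]
    mass: float
    sign: int  # +1 or -1
    p: float | None = None

    @property
    def size(self) -> int:
        return len(self.nodes)


def build_channel_adjacency(layout: "ChannelLayout",  # noqa: F821
                            subset: list[str] | None = None) -> AdjacencyGraph:
    """Neighbourhood graph from channel geometry.

    Two channels are neighbours when their 3-D distance is at most 1.5 times
    the median nearest-neighbour distance of the (sub)montage.
    """
    names = list(subset) if subset is not None else list(layout.names)
    idx = [layout.index(n) for n in names]
    pos = layout.positions[idx]
    if len(names) < 2:
        raise ValueError("need >= 2 channels with positions")
    if not np.isfinite(pos).all():
        raise ValueError("missing channel positions")
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    median_nn = float(np.median(dist.min(axis=1)))
    edges = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))
             if dist[i, j] <= 1.5 * median_nn]
    return AdjacencyGraph(len(names), tuple(edges), tuple(names))


def grid_adjacency(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """4-neighbourhood lattice (used for source-surrogate vertex meshes)."""
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((i, i + 1))
            if r + 1 < n_rows:
                edges.append((i, i + n_cols))
    return AdjacencyGraph(n_rows * n_cols, tuple(edges))


def pair_graph(layout: "ChannelLayout",  # noqa: F821
               pairs: list[tuple[str, str]]) -> AdjacencyGraph:
    """Adjacency between homologous channel pairs via their left members.

    Two pairs are neighbours when their left-hemisphere channels are
    neighbours in the montage (the montage is mirror-symmetric, so using the
    right members gives the same graph).
    """
    left_names = [p[0] for p in pairs]
    base = build_channel_adjacency(layout, subset=left_names)
    ids = tuple(f"{l}-{r}" for l, r in pairs)
    return AdjacencyGraph(len(pairs), base.edges, ids)


def product_adjacency(chan_graph: AdjacencyGraph, n_freq_bins: int) -> AdjacencyGraph:
    """Cartesian product of a channel graph with a frequency path graph.

    Node (c, f) has index c * n_freq_bins + f; (c, f) ~ (c', f) whenever
    c ~ c', and (c, f) ~ (c, f +/- 1).
    """
    if n_freq_bins < 1:
        raise ValueError("n_freq_bins must be >= 1")
    nf = n_freq_bins
    edges = []
    for c1, c2 in chan_graph.edges:
        for f in range(nf):
            edges.append((c1 * nf + f, c2 * nf + f))
    for c in range(chan_graph.n_nodes):
        for f in range(nf - 1):
            edges.append((c * nf + f, c * nf + f + 1))
    ids = None
    if chan_graph.node_ids is not None:
        ids = tuple(f"{ch}@{f}" for ch in chan_graph.node_ids for f in range(nf))
    return AdjacencyGraph(chan_graph.n_nodes * nf, tuple(edges), ids)


def node_sides_product(channels: list[str], n_freq_bins: int) -> list[str]:
    """Side label per product-space node, matching product_adjacency indexing."""
    from .layouts import channel_side

    return [channel_side(ch) for ch in channels for _ in range(n_freq_bins)]


# ---------------------------------------------------------------------------
# Clustering


def _components(mask: np.ndarray,
                neighbors: tuple[tuple[int, ...], ...]) -> list[list[int]]:
    """Connected components of the True nodes under the neighbour relation."""
    comps: list[list[int]] = []
    visited = np.zeros(len(mask), dtype=bool)
    for start in np.nonzero(mask)[0]:
        if visited[start]:
            continue
        stack = [int(start)]
        visited[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in neighbors[node]:
                if mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps


def find_clusters(stat_map: np.ndarray, threshold: float,
                  graph: AdjacencyGraph) -> list[Cluster]:
    """Suprathreshold connected components, positive and negative separately.

    Positive clusters collect nodes with stat > +threshold, negative clusters
    nodes with stat < -threshold; a cluster's mass is the sum of its members'
    statistics.  Empty output is allowed.
    """
    stat_map = np.asarray(stat_map, float)
    if stat_map.shape != (graph.n_nodes,):
        raise ValueError("stat_map must have one value per graph node")
    clusters = []
    for sign in (1, -1):
        mask = stat_map > threshold if sign == 1 else stat_map < -threshold
        for comp in _components(mask, graph.neighbors):
            nodes = tuple(sorted(comp))
            clusters.append(Cluster(nodes=nodes,
                                    mass=float(stat_map[list(comp)].sum()),
                                    sign=sign))
    return clusters


def _max_tail_masses(stat_map: np.ndarray, threshold: float,
                     neighbors) -> tuple[float, float]:
    """(max positive cluster mass, min negative cluster mass); 0 when none."""
    pos_mask = stat_map > threshold
    neg_mask = stat_map < -threshold
    max_pos = 0.0
    if pos_mask.any():
        for comp in _components(pos_mask, neighbors):
            m = float(stat_map[comp].sum())
            if m > max_pos:
                max_pos = m
    min_neg = 0.0
    if neg_mask.any():
        for comp in _components(neg_mask, neighbors):
            m = float(stat_map[comp].sum())
            if m < min_neg:
                min_neg = m
    return max_pos, min_neg


# ---------------------------------------------------------------------------
# Pointwise statistics, vectorized over permutations


def _welch_t_maps(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Welch t (group1 vs group0) per node for each assignment row of B.

    X : (subjects, nodes); B : (n_assignments, subjects) binary group-1
    indicator with a fixed row sum.  Returns (n_assignments, nodes).
    """
    n = X.shape[0]
    n1 = int(B[0].sum())
    n0 = n - n1
    total = X.sum(axis=0)
    total_sq = (X ** 2).sum(axis=0)
    s1 = B @ X
    s1_sq = B @ (X ** 2)
    m1 = s1 / n1
    m0 = (total - s1) / n0
    v1 = (s1_sq - n1 * m1 ** 2) / (n1 - 1)
    v0 = (total_sq - s1_sq - n0 * m0 ** 2) / (n0 - 1)
    v1 = np.maximum(v1, 0.0)
    v0 = np.maximum(v0, 0.0)
    denom = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _regression_t_maps(Y_res: np.ndarray, yty: np.ndarray, Xp_res: np.ndarray,
                       df: float) -> np.ndarray:
    """Slope t per node for each residualized predictor row (FWL form).

    Y_res : (subjects, nodes) outcome residualized on nuisance columns;
    yty : per-node sum of squares of Y_res; Xp_res : (n_perm, subjects)
    residualized predictors.  t = cross * sqrt(df) / sqrt(xx * yty - cross^2).
    """
    cross = Xp_res @ Y_res                     # (P, N)
    xx = (Xp_res ** 2).sum(axis=1)[:, None]    # (P, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross * math.sqrt(df) / np.sqrt(np.maximum(xx * yty - cross ** 2, 0.0))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _nuisance_projector(n: int, confounds: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if confounds is not None:
        conf = np.asarray(confounds, float)
        conf = conf[:, None] if conf.ndim == 1 else conf
        if not np.isfinite(conf).all():
            raise ValueError("confounds contain missing values; drop those "
                             "subjects before the cluster test")
        cols.append(conf)
    Z = np.column_stack(cols)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient confound design")
    return np.eye(n) - Z @ np.linalg.pinv(Z)


# ---------------------------------------------------------------------------
# The permutation test


@dataclass
class ClusterResult:
    """Outcome of one cluster-based permutation test."""

    stat_map: np.ndarray
    threshold: float
    clusters: list[Cluster]
    n_significant_points: int
    min_t: float
    max_t: float
    n_perm_used: int
    method: str  # 'exact' or 'montecarlo'
    seed: int | None
    alpha: float = 0.05

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def largest_cluster(self, by: str = "size") -> Cluster | None:
        """Most extreme cluster, ranked by member count or by |mass|."""
        if not self.clusters:
            return None
        if by == "size":
            return max(self.clusters, key=lambda c: (c.size, abs(c.mass)))
        if by == "mass":
            return max(self.clusters, key=lambda c: abs(c.mass))
        raise ValueError("by must be 'size' or 'mass'")

    @property
    def min_p(self) -> float | None:
        return min((c.p for c in self.clusters), default=None)

    def to_table_row(self) -> dict:
        """Tidy summary row: min/max t, suprathreshold counts, largest cluster."""
        largest = self.largest_cluster("size")
        return {
            "min_t": self.min_t,
            "max_t": self.max_t,
            "n_sig_points": self.n_significant_points,
            "n_clusters": self.n_clusters,
            "largest_cluster_size": largest.size if largest else np.nan,
            "largest_cluster_p": largest.p if largest else np.nan,
            "largest_cluster_mass_p": (
                self.largest_cluster("mass").p if largest else np.nan),
        }


def _enumerate_group_assignments(labels: np.ndarray,
                                 limit: int) -> np.ndarray | None:
    """All distinct binary relabelings preserving group sizes, or None if > limit."""
    n = len(labels)
    n1 = int(labels.sum())
    if math.comb(n, n1) > limit:
        return None
    rows = np.zeros((math.comb(n, n1), n))
    for r, members in enumerate(combinations(range(n), n1)):
        rows[r, list(members)] = 1.0
    return rows


def cluster_permutation_test(
    data: np.ndarray,
    predictor: np.ndarray,
    graph: AdjacencyGraph,
    kind: str = "group",
    confounds: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    two_sided_p: bool = False,
) -> ClusterResult:
    """Cluster-based permutation test of ``predictor`` against node-wise data.

    Parameters
    ----------
    data : (n_subjects, n_nodes) values on the search space.
    predictor : binary group-1 indicator (``kind='group'``) or continuous
        scores (``kind='linear'``).
    confounds : optional (n_subjects, k) covariates; when given, the
        pointwise statistic is the regression t of the predictor with the
        confounds in the model, and permutations shuffle only the predictor
        while confounds stay attached to their subjects.
    n_perm : Monte-Carlo draws; exact enumeration replaces sampling whenever
        the number of distinct relabelings is <= n_perm (p-values then have
        no Monte-Carlo error).
    two_sided_p : double tail p-values (capped at 1) for strict two-sided
        family-wise control.

    Returns a :class:`ClusterResult`; deterministic given ``seed``.
    """
    X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[1] != graph.n_nodes:
        raise ValueError("data must be (subjects, nodes) matching the graph")
    pred = np.asarray(predictor, float)
    if len(pred) != X.shape[0]:
        raise ValueError("predictor length must match n_subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    use_regression = confounds is not None or kind == "linear"
    if kind == "group":
        uniq = np.unique(pred)
        if not np.array_equal(uniq, [0.0, 1.0]):
            raise ValueError("group predictor must be binary 0/1 with both "
                             "groups present")
        n1 = int(pred.sum())
        if n1 < 2 or n - n1 < 2:
            raise ValueError("need >= 2 subjects per group")
    elif kind == "linear":
        if n < 4:
            raise ValueError("need >= 4 subjects for a linear contrast")
    else:
        raise ValueError("kind must be 'group' or 'linear'")

    # --- observed and permuted stat maps -----------------------------------
    if use_regression:
        n_conf = 0 if confounds is None else np.atleast_2d(np.asarray(confounds).T).shape[0]
        M = _nuisance_projector(n, confounds)
        Y_res = M @ X
        yty = (Y_res ** 2).sum(axis=0)
        df = float(n - n_conf - 2)  # intercept + predictor + confounds
        if df < 1:
            raise ValueError("not enough residual degrees of freedom")

        def stat_maps(pred_rows: np.ndarray) -> np.ndarray:
            return _regression_t_maps(Y_res, yty, pred_rows @ M.T, df)
    else:
        df = float(n - 2)

        def stat_maps(pred_rows: np.ndarray) -> np.ndarray:
            return _welch_t_maps(X, pred_rows)

    threshold = float(sps.t.ppf(1.0 - alpha / 2.0, df))

    # --- relabelings --------------------------------------------------------
    exact_rows: np.ndarray | None = None
    if kind == "group":
        exact_rows = _enumerate_group_assignments(pred, n_perm)
    else:
        if n <= 8 and math.factorial(n) <= n_perm:
            exact_rows = np.array([np.take(pred, p)
                                   for p in permutations(range(n))])

    if exact_rows is not None:
        perm_rows = exact_rows
        method = "exact"
    else:
        perm_rows = np.empty((n_perm, n))
        for r in range(n_perm):
            perm_rows[r] = pred[rng.permutation(n)]
        method = "montecarlo"

    obs_map = stat_maps(pred[None, :])[0]
    null_maps = stat_maps(perm_rows)

    # --- clusters and tail nulls -------------------------------------------
    nbrs = graph.neighbors
    obs_clusters = find_clusters(obs_map, threshold, graph)
    abs_supra = np.abs(null_maps) > threshold
    any_supra = abs_supra.any(axis=1)
    n_draws = null_maps.shape[0]
    null_pos = np.zeros(n_draws)
    null_neg = np.zeros(n_draws)
    for r in np.nonzero(any_supra)[0]:
        null_pos[r], null_neg[r] = _max_tail_masses(null_maps[r], threshold, nbrs)

    clusters = []
    for cl in obs_clusters:
        if cl.sign == 1:
            b = int((null_pos >= cl.mass - 1e-12).sum())
        else:
            b = int((null_neg <= cl.mass + 1e-12).sum())
        if method == "exact":
            p = b / n_draws  # enumeration includes the identity relabeling
        else:
            p = (1.0 + b) / (1.0 + n_draws)
        if two_sided_p:
            p = min(1.0, 2.0 * p)
        clusters.append(Cluster(cl.nodes, cl.mass, cl.sign, p=float(p)))

    n_sig_points = int((np.abs(obs_map) > threshold).sum())
    return ClusterResult(
        stat_map=obs_map,
        threshold=threshold,
        clusters=clusters,
        n_significant_points=n_sig_points,
        min_t=float(obs_map.min()),
        max_t=float(obs_map.max()),
        n_perm_used=n_draws,
        method=method,
        seed=seed,
        alpha=alpha,
    )


def cluster_asymmetry_test(cluster: Cluster, node_sides: list[str]) -> "TestResult":  # noqa: F821
    """Chi-square follow-up: is a cluster lateralized?

    Compares the share of left-side search-space nodes belonging to the
    cluster against the right-side share (midline nodes excluded from both
    margins).  chi2(1) = 0, p = 1 for a perfectly mirror-symmetric cluster.
    """
    from .stats import chi2_two_proportions

    if not cluster.nodes:
        raise ValueError("empty cluster")
    sides = np.asarray(node_sides)
    if len(sides) <= max(cluster.nodes):
        raise ValueError("node_sides must cover every node index")
    left_total = int((sides == "left").sum())
    right_total = int((sides == "right").sum())
    if left_total == 0 or right_total == 0:
        raise ValueError("search space must contain both left and right nodes")
    members = np.zeros(len(sides), dtype=bool)
    members[list(cluster.nodes)] = True
    k_left = int((members & (sides == "left")).sum())
    k_right = int((members & (sides == "right")).sum())
    return chi2_two_proportions(k_left, left_total, k_right, right_total)
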