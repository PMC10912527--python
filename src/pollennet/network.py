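"""Bipartite plant-pollinator network metrics.

Implements the standardized two-dimensional Shannon entropy index of
network-level specialization (H2'), the standardized Kullback-Leibler
species-level specialization (d'), species strength, closeness centrality,
and Chao1 sampling completeness, on a weighted (or binarized, "qualitative")
plant x pollinator interaction matrix.

All entropies use natural logarithms.  The normalizations follow the
convention of standardizing the observed index between its minimum and
maximum attainable values given the matrix marginals: specialized = 1,
perfectly opportunistic (marginal-proportional) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "build_network",
    "links_per_species",
    "min_entropy_given_marginals",
    "H2Result",
    "h2_prime",
    "d_prime",
    "species_strength",
    "closeness_centrality",
    "Chao1Result",
    "chao1_completeness",
]


@dataclass(frozen=True)
class BipartiteNetwork:
    """Weighted bipartite interaction matrix with species labels.

    Rows are plant species, columns are pollinator (flower-visitor)
    species; ``matrix[i, j]`` is the interaction weight (visit count, or 1
    in a qualitative network).
    """

    matrix: np.ndarray
    plants: tuple[str, ...]
    pollinators: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("interaction matrix must be 2-dimensional")
        if (m < 0).any():
            raise ValueError("interaction weights must be non-negative")
        if m.sum() <= 0:
            raise ValueError("interaction matrix must have positive total weight")
        if len(self.plants) != m.shape[0] or len(self.pollinators) != m.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.plants)) != len(self.plants):
            raise ValueError("duplicate plant labels")
        if len(set(self.pollinators)) != len(self.pollinators):
            raise ValueError("duplicate pollinator labels")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "plants", tuple(self.plants))
        object.__setattr__(self, "pollinators", tuple(self.pollinators))

    @property
    def n_plants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.matrix.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    @property
    def n_links(self) -> int:
        """Number of realized (positive-weight) plant-pollinator links."""
        return int((self.matrix > 0).sum())

    def binarize(self) -> "BipartiteNetwork":
        """Qualitative copy: every positive weight replaced by 1."""
        return BipartiteNetwork((self.matrix > 0).astype(float), self.plants, self.pollinators)

    def to_graph(self) -> nx.Graph:
        """Unweighted graph on plant + pollinator nodes, edge where a_ij > 0."""
        g = nx.Graph()
        g.add_nodes_from((("plant", p) for p in self.plants))
        g.add_nodes_from((("pollinator", q) for q in self.pollinators))
        rows, cols = np.nonzero(self.matrix)
        g.add_edges_from(
            (("plant", self.plants[i]), ("pollinator", self.pollinators[j]))
            for i, j in zip(rows, cols)
        )
        return g


def build_network(
    edges: Iterable[tuple[str, str, float]] | pd.DataFrame,
    binarize: bool = False,
) -> BipartiteNetwork:
    """Assemble a :class:`BipartiteNetwork` from (plant, pollinator, weight) edges.

    Duplicate edges are summed.  With ``binarize=True`` all positive weights
    are replaced by 1 (the qualitative-network convention).
    """
    if isinstance(edges, pd.DataFrame):
        rows = list(edges[["plant", "pollinator", "weight"]].itertuples(index=False, name=None))
    else:
        rows = [(p, q, w) for p, q, w in edges]
    if not rows:
        raise ValueError("empty edge list")
    plants = sorted({p for p, _, _ in rows})
    pollinators = sorted({q for _, q, _ in rows})
    pi = {p: i for i, p in enumerate(plants)}
    qi = {q: j for j, q in enumerate(pollinators)}
    mat = np.zeros((len(plants), len(pollinators)))
    for p, q, w in rows:
        mat[pi[p], qi[q]] += w
    net = BipartiteNetwork(mat, tuple(plants), tuple(pollinators))
    return net.binarize() if binarize else net


def links_per_species(network: BipartiteNetwork) -> float:
    """Realized links divided by total species count (both modes)."""
    return network.n_links / (network.n_plants + network.n_pollinators)


# ---------------------------------------------------------------------------
# Entropy machinery


def _entropy(values: np.ndarray, total: float) -> float:
    """Shannon entropy -sum (a/m) ln(a/m) over positive entries, 0 ln 0 = 0."""
    p = np.asarray(values, dtype=float).ravel()
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def greedy_min_entropy_allocation(
    row_totals: Sequence[int], col_totals: Sequence[int]
) -> np.ndarray:
    """Greedy maximal-concentration matrix with the given integer marginals.

    Repeatedly allocates ``min(remaining row, remaining column)`` to a
    single cell, preferring allocations that exhaust a row and a column
    simultaneously (largest such first) and otherwise taking the largest
    allocation; ties broken by lowest row index, then lowest column index.
    Concentrating weight into few large cells minimizes joint entropy; the
    exact-match preference keeps totals that can be consumed whole from
    being split by a larger overlapping allocation.  A margin-preserving
    2x2 transfer polish runs afterwards.
    """
    r = np.asarray(row_totals, dtype=np.int64).copy()
    c = np.asarray(col_totals, dtype=np.int64).copy()
    if r.sum() != c.sum():
        raise ValueError("row and column totals must agree")
    out = np.zeros((len(r), len(c)), dtype=np.int64)
    while True:
        alloc = np.minimum.outer(r, c)
        best = alloc.max()
        if best <= 0:
            break
        exact = (r[:, None] == c[None, :]) & (alloc > 0)
        if exact.any():
            masked = np.where(exact, alloc, 0)
            i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        else:
            i, j = np.unravel_index(int(np.argmax(alloc)), alloc.shape)
        take = alloc[i, j]
        out[i, j] += take
        r[i] -= take
        c[j] -= take
    return _swap_polish(out)


def _swap_polish(mat: np.ndarray) -> np.ndarray:
    """Margin-preserving 2x2 transfer local search lowering joint entropy.

    The pure concentration pass is not always optimal (its first move can
    split a row total that an optimal matrix keeps intact), so we polish:
    move delta grains from cells (i,j),(k,l) to (i,l),(k,j), which leaves
    both marginals unchanged, whenever that lowers the entropy; repeat with
    the best improving move until none exists.
    """
    mat = mat.copy()
    m = mat.sum()

    def f(a: np.int64) -> float:
        return 0.0 if a <= 0 else -(a / m) * math.log(a / m)

    while True:
        donors = np.argwhere(mat > 0)
        best_gain, best_move = 1e-12, None
        for di in range(len(donors)):
            i, j = donors[di]
            for dk in range(len(donors)):
                k, l = donors[dk]
                if i == k or j == l:
                    continue
                a_ij, a_kl, a_il, a_kj = mat[i, j], mat[k, l], mat[i, l], mat[k, j]
                base = f(a_ij) + f(a_kl) + f(a_il) + f(a_kj)
                for delta in range(1, int(min(a_ij, a_kl)) + 1):
                    gain = base - (
                        f(a_ij - delta) + f(a_kl - delta) + f(a_il + delta) + f(a_kj + delta)
                    )
                    if gain > best_gain:
                        best_gain = gain
                        best_move = (i, j, k, l, delta)
        if best_move is None:
            return mat
        i, j, k, l, delta = best_move
        mat[i, j] -= delta
        mat[k, l] -= delta
        mat[i, l] += delta
        mat[k, j] += delta


class _NodeBudgetExceeded(Exception):
    pass


def min_entropy_given_marginals(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    node_budget: int = 200_000,
) -> float:
    """Minimum joint entropy over integer matrices with the given marginals.

    Finding the minimum-entropy contingency table is a combinatorial
    (subset-sum-like) problem: no myopic allocation rule is exact.  This
    routine seeds an incumbent with the greedy concentration + swap polish
    of :func:`greedy_min_entropy_allocation`, then runs a depth-first
    branch-and-bound that allocates one row total at a time over the
    remaining column totals, pruning with the subadditivity bound
    ``sum_i f(r_i)`` (a row's mass split over several cells never
    contributes less entropy than the unsplit row; likewise for columns).
    Rows and columns with equal remaining totals are exchangeable, so
    states are kept as sorted multisets.  Small problems are solved to
    optimality; when ``node_budget`` is exhausted (large networks) the best
    matrix found so far — at worst the polished greedy — is returned.
    """
    r0 = tuple(sorted((int(x) for x in row_totals if x > 0), reverse=True))
    c0 = tuple(sorted((int(x) for x in col_totals if x > 0), reverse=True))
    if sum(r0) != sum(c0):
        raise ValueError("row and column totals must agree")
    m = sum(r0)
    mat = greedy_min_entropy_allocation(r0, c0)
    incumbent = _entropy(mat, m)

    def f(a: int) -> float:
        return 0.0 if a <= 0 else -(a / m) * math.log(a / m)

    state = {"best": incumbent, "nodes": 0}

    def dfs(rows: tuple[int, ...], cols: tuple[int, ...], acc: float) -> None:
        state["nodes"] += 1
        if state["nodes"] > node_budget:
            raise _NodeBudgetExceeded
        if not rows:
            if acc < state["best"] - 1e-12:
                state["best"] = acc
            return
        lb = max(sum(f(x) for x in rows), sum(f(x) for x in cols))
        if acc + lb >= state["best"] - 1e-12:
            return
        target, rest = rows[0], rows[1:]
        k = len(cols)

        # enumerate allocations of `target` over the column multiset,
        # non-increasing among equal columns to skip exchangeable duplicates
        def rec(i: int, left: int, alloc: list[int], cell_acc: float) -> None:
            if acc + cell_acc >= state["best"] - 1e-12:
                return
            if left == 0:
                new_cols = tuple(
                    sorted(
                        (cols[j] - (alloc[j] if j < len(alloc) else 0) for j in range(k)),
                        reverse=True,
                    )
                )
                new_cols = tuple(x for x in new_cols if x > 0)
                dfs(rest, new_cols, acc + cell_acc)
                return
            if i == k:
                return
            hi = min(left, cols[i])
            if i > 0 and cols[i] == cols[i - 1] and i - 1 < len(alloc):
                hi = min(hi, alloc[i - 1])
            for a in range(hi, -1, -1):
                alloc.append(a)
                rec(i + 1, left - a, alloc, cell_acc + f(a))
                alloc.pop()

        rec(0, target, [], 0.0)

    try:
        dfs(r0, c0, 0.0)
    except _NodeBudgetExceeded:
        pass
    return state["best"]


@dataclass(frozen=True)
class H2Result:
    """Observed, maximum, minimum two-dimensional entropy and standardized H2'."""

    observed: float
    maximum: float
    minimum: float
    h2_prime: float


def h2_prime(network: BipartiteNetwork) -> H2Result:
    """Network-level specialization H2' = (H2max - H2obs) / (H2max - H2min).

    ``H2obs`` is the Shannon entropy of the joint interaction frequencies;
    ``H2max`` is the entropy of the outer product of the marginal
    frequencies (the exact supremum, attained under marginal independence);
    ``H2min`` is the minimum entropy over non-negative integer matrices with
    the observed integer marginals, found by the greedy concentration
    allocation.  H2' = 0 when the maximum and minimum coincide.
    """
    m = network.total
    h_obs = _entropy(network.matrix, m)
    pr = network.row_totals / m
    pc = network.col_totals / m
    h_max = _entropy(pr, 1.0) + _entropy(pc, 1.0)
    r, c = network.row_totals, network.col_totals
    if not (np.allclose(r, np.round(r)) and np.allclose(c, np.round(c))):
        raise ValueError(
            "integer-constrained H2min requires integer marginals; "
            "round the weights or binarize the network"
        )
    h_min = min_entropy_given_marginals(
        np.round(r).astype(np.int64), np.round(c).astype(np.int64)
    )
    if h_max - h_min <= 1e-12:
        h2p = 0.0
    else:
        h2p = (h_max - h_obs) / (h_max - h_min)
        h2p = min(max(h2p, 0.0), 1.0)
    return H2Result(h_obs, h_max, h_min, h2p)


def _kl_d(counts: np.ndarray, q: np.ndarray) -> float:
    """d_i = sum_j p'_ij ln(p'_ij / q_j) for one species' partner counts."""
    a = np.asarray(counts, dtype=float)
    tot = a.sum()
    mask = a > 0
    p = a[mask] / tot
    return float((p * np.log(p / q[mask])).sum())


def min_kl_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` grains across partners minimizing d.

    Starts from the rounded proportional-to-availability allocation, then
    repairs by single-grain moves while any move lowers d.  The objective is
    separable convex over the integer simplex, so single-grain local search
    terminates at the global minimum.
    """
    q = np.asarray(q, dtype=float)
    k = len(q)
    alloc = np.floor(total * q).astype(np.int64)
    deficit = total - alloc.sum()
    if deficit > 0:
        frac = total * q - np.floor(total * q)
        for j in np.argsort(-frac)[:deficit]:
            alloc[j] += 1

    def d_of(a: np.ndarray) -> float:
        return _kl_d(a, q)

    current = d_of(alloc)
    improved = True
    while improved:
        improved = False
        donors = np.nonzero(alloc > 0)[0]
        best_move, best_val = None, current
        for s in donors:
            for t in range(k):
                if t == s:
                    continue
                alloc[s] -= 1
                alloc[t] += 1
                val = d_of(alloc)
                alloc[s] += 1
                alloc[t] -= 1
                if val < best_val - 1e-15:
                    best_val, best_move = val, (s, t)
        if best_move is not None:
            s, t = best_move
            alloc[s] -= 1
            alloc[t] += 1
            current = best_val
            improved = True
    return alloc


def d_prime(
    network: BipartiteNetwork,
    level: Literal["plants", "pollinators"] = "plants",
    continuous_dmin: bool = False,
) -> pd.DataFrame:
    """Species-level specialization d' for one mode of the network.

    For species i (say a plant), ``d = sum_j p'_ij ln(p'_ij / q_j)`` where
    ``p'_ij`` is its partner-use distribution and ``q_j`` the partners'
    availability (column totals / grand total).  ``d_max = ln(m / A_i)``;
    ``d_min`` is the minimum of d over integer allocations of the species'
    A_i interactions (or 0 with ``continuous_dmin=True``).  Species with no
    interactions are omitted.

    Returns a DataFrame indexed by species with columns
    ``d, d_min, d_max, d_prime, degree``.
    """
    if level == "plants":
        mat, labels = network.matrix, network.plants
    elif level == "pollinators":
        mat, labels = network.matrix.T, network.pollinators
    else:
        raise ValueError("level must be 'plants' or 'pollinators'")
    m = mat.sum()
    q = mat.sum(axis=0) / m
    rows = []
    for i, label in enumerate(labels):
        a = mat[i]
        tot = a.sum()
        if tot <= 0:
            continue
        d = _kl_d(a, q)
        d_max = math.log(m / tot)
        if continuous_dmin:
            d_min = 0.0
        else:
            if not np.allclose(tot, round(tot)):
                raise ValueError(
                    "integer d_min requires integer totals; use continuous_dmin=True"
                )
            d_min = _kl_d(min_kl_allocation(int(round(tot)), q), q)
        if d_max - d_min <= 1e-12:
            dp = 0.0
        else:
            dp = min(max((d - d_min) / (d_max - d_min), 0.0), 1.0)
        rows.append(
            {
                "species": label,
                "d": d,
                "d_min": d_min,
                "d_max": d_max,
                "d_prime": dp,
                "degree": int((a > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("species")


def species_strength(
    network: BipartiteNetwork, level: Literal["plants", "pollinators"] = "plants"
) -> pd.Series:
    """Sum of partner dependencies on each species.

    For plant i: ``sum_j a_ij / A_j`` over pollinators j — each pollinator's
    fraction of interactions devoted to plant i.  Plant strengths sum to the
    number of pollinator species (each pollinator's dependencies sum to 1).
    """
    mat = network.matrix if level == "plants" else network.matrix.T
    labels = network.plants if level == "plants" else network.pollinators
    partner_totals = mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dep = np.where(partner_totals > 0, mat / partner_totals, 0.0)
    return pd.Series(dep.sum(axis=1), index=list(labels), name="strength")


def closeness_centrality(
    network: BipartiteNetwork, variant: Literal["standard", "harmonic"] = "standard"
) -> pd.DataFrame:
    """Closeness centrality of every node in the two-mode graph.

    ``standard``: (k-1)/sum of within-component distances for a node in a
    component of size k (0 for isolated nodes); ``harmonic``: mean of
    reciprocal distances, 1/(n-1) * sum 1/dist.  Returns a DataFrame with
    columns ``mode, species, closeness``.
    """
    g = network.to_graph()
    n = g.number_of_nodes()
    if variant == "standard":
        cc = nx.closeness_centrality(g, wf_improved=False)
    elif variant == "harmonic":
        cc = {u: v / (n - 1) for u, v in nx.harmonic_centrality(g).items()}
    else:
        raise ValueError("variant must be 'standard' or 'harmonic'")
    rows = [
        {"mode": mode, "species": label, "closeness": cc[(mode, label)]}
        for mode, label in g.nodes
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Chao1Result:
    """Chao1 richness estimate and derived sampling completeness."""

    s_obs: int
    f1: int
    f2: int
    estimate: float
    completeness: float  # percent, 100 * S_obs / estimate
    variant: str = "bias_corrected"


def chao1_completeness(
    abundances: Sequence[int],
    variant: Literal["classic", "bias_corrected"] = "bias_corrected",
) -> Chao1Result:
    """Chao1 species-richness estimator and sampling completeness (%).

    classic: S_obs + f1^2 / (2 f2), falling back to S_obs + f1(f1-1)/2 when
    there are no doubletons; bias-corrected:
    S_obs + ((n-1)/n) * f1(f1-1) / (2(f2+1)), n = total count.
    """
    a = np.asarray(abundances, dtype=np.int64)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative integers")
    if a.sum() == 0:
        raise ValueError("all-zero abundance vector")
    s_obs = int((a > 0).sum())
    f1 = int((a == 1).sum())
    f2 = int((a == 2).sum())
    n = int(a.sum())
    if variant == "classic":
        if f2 > 0:
            est = s_obs + f1 * f1 / (2.0 * f2)
        else:
            est = s_obs + f1 * (f1 - 1) / 2.0
    elif variant == "bias_corrected":
        est = s_obs + (n - 1) / n * f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        raise ValueError("variant must be 'classic' or 'bias_corrected'")
    return Chao1Result(s_obs, f1, f2, est, 100.0 * s_obs / est, variant)
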