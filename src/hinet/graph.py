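"""Graph-theoretic characterization of the heartbeat-induced network.

Hubs (strength, betweenness on 1/weight path lengths), consensus Louvain
modularity with an agreement-matrix iteration, a weight-preserving random
null for modularity significance, within-module degree z / participation
coefficient role classification, module-level synchronization and
between-module interaction graphs, hemispheric asymmetry, and the HIN
synchronization time course.

Modularity follows Q = 1/(2 mu) * sum_ij [A_ij - gamma * P_ij] delta(g_i, g_j)
with the configuration-model null P_ij = s_i s_j / (2 mu), where 2 mu is the
total (double-counted) edge weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "ModularityResult",
    "ModuleGraph",
    "NodeMetrics",
    "ConsensusError",
    "node_strength",
    "betweenness",
    "modularity_q",
    "louvain",
    "consensus_partition",
    "modularity_significance",
    "z_p_roles",
    "node_metrics",
    "module_sync",
    "between_module_graph",
    "hemispheric_asymmetry",
    "sync_timecourse",
]

Z_HUB_THRESHOLD = 2.5
P_CONNECTOR_THRESHOLD = 0.3


class ConsensusError(RuntimeError):
    """Consensus partitioning failed to converge; carries the last agreement matrix."""

    def __init__(self, msg, agreement=None):
        super().__init__(msg)
        self.agreement = agreement


@dataclass
class ModularityResult:
    partition: np.ndarray  # module label per node, contiguous from 1
    q: float
    gamma: float
    agreement: np.ndarray
    tau: float
    n_runs: int
    n_iterations: int

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.partition).size)


@dataclass
class ModuleGraph:
    between_sync: np.ndarray  # modules x modules, inter-module weight sums
    within_sync: np.ndarray  # per-module within weight sums
    module_strength: np.ndarray
    module_betweenness: np.ndarray
    modules: np.ndarray  # module ids, row order of the matrices


@dataclass
class NodeMetrics:
    strength: np.ndarray
    betweenness: np.ndarray
    z: np.ndarray
    participation: np.ndarray
    role: list = field(default_factory=list)
    module: np.ndarray | None = None


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10 * max(1.0, np.abs(W).max())):
        raise ValueError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def node_strength(W: np.ndarray) -> np.ndarray:
    """Sum of the weights of all edges incident to each node."""
    return _check_weights(W).sum(axis=1)


def _weighted_graph(W: np.ndarray) -> nx.Graph:
    n = W.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if W[i, j] > 0:
            g.add_edge(int(i), int(j), weight=float(W[i, j]), length=1.0 / float(W[i, j]))
    return g


def betweenness(W: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness centrality.

    Shortest paths use edge lengths 1/weight (stronger synchronization =
    shorter path); counts are raw pair-dependency sums, so on an n-node
    connected graph the values can be of order n^2. Unreachable pairs in a
    disconnected graph simply contribute nothing.
    """
    W = _check_weights(W)
    g = _weighted_graph(W)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(W.shape[0])])


def modularity_q(W: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Q of a given partition under the configuration-model null."""
    W = _check_weights(W)
    labels = np.asarray(partition)
    two_mu = W.sum()
    if two_mu == 0:
        raise ValueError("graph has no edges")
    s = W.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    b = W - gamma * np.outer(s, s) / two_mu
    return float(b[same].sum() / two_mu)


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..k in order of first appearance."""
    out = np.zeros(labels.size, dtype=np.int64)
    mapping: dict = {}
    for idx, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[idx] = mapping[lab]
    return out


def louvain(
    W: np.ndarray, gamma: float = 1.0, seed: int | None = None
) -> tuple[np.ndarray, float]:
    """One Louvain run; returns (labels contiguous from 1, Q on W)."""
    W = _check_weights(W)
    if W.shape[0] == 0 or W.sum() == 0:
        raise ValueError("empty graph")
    g = _weighted_graph(W)
    comms = nx.community.louvain_communities(g, weight="weight", resolution=gamma, seed=seed)
    labels = np.zeros(W.shape[0], dtype=np.int64)
    for k, comm in enumerate(comms):
        for v in comm:
            labels[v] = k
    labels = _contiguous(labels)
    return labels, modularity_q(W, labels, gamma)


def consensus_partition(
    W: np.ndarray,
    n_runs: int = 10000,
    tau: float = 0.2,
    seed: int | None = None,
    gamma: float = 1.0,
    max_iterations: int = 20,
) -> ModularityResult:
    """Consensus Louvain partition via thresholded agreement matrices.

    Iterate: run Louvain ``n_runs`` times, build the co-assignment fraction
    matrix D, zero entries below ``tau``, re-partition D — until D is binary
    block-diagonal (all runs agree). Q is reported for the converged
    partition on the ORIGINAL weight matrix.
    """
    W = _check_weights(W)
    rng = np.random.default_rng(seed)
    current = W
    agreement = None
    for it in range(1, max_iterations + 1):
        d = np.zeros_like(W)
        first_labels = None
        for _ in range(n_runs):
            labels, _q = louvain(current, gamma=gamma, seed=int(rng.integers(2**31)))
            if first_labels is None:
                first_labels = labels
            d += labels[:, None] == labels[None, :]
        d /= n_runs
        agreement = d
        off = d[~np.eye(d.shape[0], dtype=bool)]
        if np.all((off < 1e-12) | (off > 1 - 1e-12)):
            # block diagonal: read the final partition off the agreement matrix
            from scipy.sparse.csgraph import connected_components as _cc
            _, comp = _cc(d > 0.5, directed=False)
            partition = _contiguous(comp)
            return ModularityResult(
                partition=partition,
                q=modularity_q(W, partition, gamma),
                gamma=gamma,
                agreement=d,
                tau=tau,
                n_runs=n_runs,
                n_iterations=it,
            )
        d = d.copy()
        d[d < tau] = 0.0
        np.fill_diagonal(d, 0.0)
        if d.sum() == 0:
            raise ConsensusError("agreement matrix thresholded to empty", agreement)
        current = d
    raise ConsensusError(
        f"consensus did not converge within {max_iterations} iterations", agreement
    )


def _random_weight_preserving(
    W: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Null network: the same weight multiset on randomly chosen edge slots."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = W[iu, ju]
    weights = vals[vals > 0]
    m = weights.size
    slots = rng.choice(iu.size, size=m, replace=False)
    shuffled = rng.permutation(weights)
    out = np.zeros_like(W)
    out[iu[slots], ju[slots]] = shuffled
    return out + out.T


def modularity_significance(
    W: np.ndarray,
    n_random: int = 100,
    seed: int | None = None,
    n_runs: int = 100,
    tau: float = 0.2,
    gamma: float = 1.0,
):
    """Monte Carlo test of modularity against weight-preserving random networks.

    Each null preserves the node count, edge count and exact weight multiset;
    consensus Q is computed per null (at the given, typically reduced,
    ``n_runs``). Returns (observed Q, null Q array, p = fraction of null Q >=
    observed).
    """
    W = _check_weights(W)
    if W.sum() == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    obs = consensus_partition(W, n_runs=n_runs, tau=tau, seed=int(rng.integers(2**31)), gamma=gamma)
    null_q = np.empty(n_random)
    for k in range(n_random):
        wn = _random_weight_preserving(W, rng)
        try:
            null_q[k] = consensus_partition(
                wn, n_runs=n_runs, tau=tau, seed=int(rng.integers(2**31)), gamma=gamma
            ).q
        except ConsensusError:
            # fall back to the best single-run Q for this null network
            null_q[k] = max(
                louvain(wn, gamma=gamma, seed=int(rng.integers(2**31)))[1] for _ in range(n_runs)
            )
    p = float((null_q >= obs.q).mean())
    return obs.q, null_q, p


def z_p_roles(W: np.ndarray, partition: np.ndarray) -> NodeMetrics:
    """Within-module degree z-score, participation coefficient, node roles.

    z uses the population SD within each module (so module z-scores have mean
    0, SD 1 by construction); singleton or zero-variance modules get z = 0
    with a warning. Connector hubs satisfy z > 2.5 and P > 0.3.
    """
    W = _check_weights(W)
    labels = np.asarray(partition)
    if labels.shape != (W.shape[0],):
        raise ValueError("partition must label every node")
    modules = np.unique(labels)
    s = W.sum(axis=1)
    kappa = np.stack([W[:, labels == m].sum(axis=1) for m in modules], axis=1)  # node x module

    z = np.zeros(W.shape[0])
    for mi, m in enumerate(modules):
        members = labels == m
        vals = kappa[members, mi]
        if vals.size == 1:
            warnings.warn(f"module {m} is a singleton; z set to 0")
            continue
        sd = vals.std()
        if sd == 0:
            continue
        z[members] = (vals - vals.mean()) / sd

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s[:, None] > 0, kappa / np.where(s[:, None] > 0, s[:, None], 1.0), 0.0)
    participation = np.where(s > 0, 1.0 - (frac**2).sum(axis=1), 0.0)

    roles = []
    for zi, pi in zip(z, participation):
        hub = zi > Z_HUB_THRESHOLD
        conn = pi > P_CONNECTOR_THRESHOLD
        roles.append(
            "connector_hub" if hub and conn
            else "provincial_hub" if hub
            else "connector_nonhub" if conn
            else "peripheral_nonhub"
        )
    return NodeMetrics(
        strength=s,
        betweenness=np.array([]),
        z=z,
        participation=participation,
        role=roles,
        module=labels,
    )


def node_metrics(W: np.ndarray, partition: np.ndarray | None = None, region_labels=None):
    """Per-node metrics table (region, strength, BC, module, z, P, role)."""
    import pandas as pd

    W = _check_weights(W)
    s = node_strength(W)
    bc = betweenness(W)
    data = {
        "region": region_labels if region_labels is not None else list(range(W.shape[0])),
        "strength": s,
        "betweenness": bc,
    }
    if partition is not None:
        zp = z_p_roles(W, partition)
        data["module"] = np.asarray(partition)
        data["z"] = zp.z
        data["participation"] = zp.participation
        data["role"] = zp.role
    return pd.DataFrame(data)


def module_sync(W: np.ndarray, partition: np.ndarray) -> dict:
    """Sum of edge weights with both endpoints inside each module."""
    W = _check_weights(W)
    labels = np.asarray(partition)
    out = {}
    iu, ju = np.triu_indices(W.shape[0], k=1)
    for m in np.unique(labels):
        sel = (labels[iu] == m) & (labels[ju] == m)
        out[int(m)] = float(W[iu[sel], ju[sel]].sum())
    return out


def module_sync_timecourses(stack, his_edges: list, partition: np.ndarray) -> dict:
    """Per-module time course: sum of the wPLI-D stack over within-module HIN edges."""
    labels = np.asarray(partition)
    out = {}
    for m in np.unique(labels):
        edges = [(i, j) for i, j in his_edges if labels[i] == m and labels[j] == m]
        tc = np.zeros(stack.time_points.size)
        for i, j in edges:
            tc += stack.wpli_d[i, j, :]
        out[int(m)] = tc
    return out


def between_module_graph(W: np.ndarray, partition: np.ndarray) -> ModuleGraph:
    """Module-level interaction graph with strength and betweenness."""
    W = _check_weights(W)
    labels = np.asarray(partition)
    modules = np.unique(labels)
    if modules.size < 2:
        raise ValueError("need at least 2 modules")
    m = modules.size
    between = np.zeros((m, m))
    iu, ju = np.triu_indices(W.shape[0], k=1)
    mod_index = {int(mm): k for k, mm in enumerate(modules)}
    for i, j in zip(iu, ju):
        if W[i, j] == 0:
            continue
        a, b = mod_index[int(labels[i])], mod_index[int(labels[j])]
        if a != b:
            between[a, b] += W[i, j]
            between[b, a] += W[i, j]
    within = np.array([module_sync(W, labels)[int(mm)] for mm in modules])
    return ModuleGraph(
        between_sync=between,
        within_sync=within,
        module_strength=node_strength(between),
        module_betweenness=betweenness(between),
        modules=modules,
    )


def hemispheric_asymmetry(left_sync: np.ndarray, right_sync: np.ndarray):
    """Paired t across subjects of left vs right within-hemisphere synchronization."""
    left = np.asarray(left_sync, dtype=float)
    right = np.asarray(right_sync, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("need matched per-subject left/right vectors")
    if left.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.all(left == right):
        return 0.0, 1.0
    t, p = stats.ttest_rel(left, right)
    return float(t), float(p)


def sync_timecourse(
    stack, his_edges: list, baseline_window: tuple | None = None
) -> np.ndarray:
    """Summed wPLI-D over the HIN edges at every stack time point."""
    if not his_edges:
        raise ValueError("empty edge set")
    tc = np.zeros(stack.time_points.size)
    for i, j in his_edges:
        tc += stack.wpli_d[i, j, :]
    if baseline_window is not None:
        w0, w1 = baseline_window
        sel = (stack.time_points >= w0 - 1e-6) & (stack.time_points <= w1 + 1e-6)
        if not sel.any():
            raise ValueError("baseline window contains no time points")
        tc = tc - tc[sel].mean()
    return tc
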