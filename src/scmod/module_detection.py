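"""Co-expression module detection on a pruned subtype network.

The weighted adjacency a_ij = |cor_ij|^beta (zero on non-significant
edges) is soft-thresholded at the smallest beta giving an approximately
scale-free connectivity distribution, turned into a topological-overlap
dissimilarity, and cut with average-linkage hierarchical clustering at
a fixed height. Clusters below the minimum size fall into Module0, the
residual bin for unclustered genes; real modules are numbered 1..Sn by
decreasing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .coexpression import AggregatedNetwork

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """gene -> module index map for one subtype; 0 means unassigned."""

    subtype: str
    assignment: dict
    beta: float
    r2: float

    @property
    def n_modules(self) -> int:
        mods = set(self.assignment.values()) - {0}
        return len(mods)

    def module_genes(self, module: int) -> set:
        return {g for g, m in self.assignment.items() if m == module}

    def modules(self) -> list[int]:
        """Non-trivial module indices 1..Sn."""
        return sorted(set(self.assignment.values()) - {0})


def _masked_abs_cor(net: AggregatedNetwork) -> np.ndarray:
    if net.significant is None:
        raise ValueError("network must be pruned before module detection")
    a = np.abs(net.cor) * net.significant
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width bins of k.

    Positive slope flips the sign, so only connectivity distributions
    that *decay* in k can score well — the scale-free criterion.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < 4 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    fit = stats.linregress(xs, ys)
    r2 = fit.rvalue ** 2
    return -r2 if fit.slope > 0 else r2


def pick_soft_threshold(
    net: AggregatedNetwork,
    candidates=None,
    r2_target: float = 0.8,
    adjacency_floor: float = 0.05,
    fallback_beta: int = 6,
) -> tuple[float, float]:
    """Smallest admissible beta whose connectivity fit reaches r2_target.

    Connectivity is k_i = sum_j |cor_ij|^beta over significant edges.
    On networks of a few hundred genes the scale-free fit alone cannot
    anchor the power: its R^2 keeps rising toward extreme betas, where
    |cor|^beta adjacency collapses and a downstream static tree cut
    (at height 1 - adjacency_floor) can no longer form any module.
    Candidates are therefore capped where the lower-quartile
    significant edge keeps an adjacency of at least twice the floor,
    so the weakest real module stays clusterable. Within the cap the
    smallest beta reaching the R^2 target wins; if none does, the
    canonical unsigned-network default power is used, clamped into the
    cap. Degenerate networks (constant connectivity at every beta)
    return beta 1 with r2 0.
    """
    if candidates is None:
        candidates = list(range(1, 21))
    if any(b <= 0 for b in candidates):
        raise ValueError("candidate betas must be positive")
    candidates = sorted(candidates)
    base = _masked_abs_cor(net)
    edge_vals = base[np.triu_indices_from(base, k=1)]
    edge_vals = edge_vals[edge_vals > 0]
    if edge_vals.size == 0:
        logger.warning("%s: no significant edges, beta=1", net.subtype)
        return 1.0, 0.0
    q25 = float(np.quantile(edge_vals, 0.25))
    window = [
        b for b in candidates if q25 >= 1.0 or q25**b >= 2.0 * adjacency_floor
    ] or candidates[:1]
    fits = [(b, scale_free_fit(np.power(base, b).sum(axis=1))) for b in window]
    if all(r2 == 0.0 for _, r2 in fits):
        logger.warning("%s: degenerate connectivity, beta=%d", net.subtype, window[0])
        return float(window[0]), 0.0
    for beta, r2 in fits:
        if r2 >= r2_target:
            return float(beta), float(r2)
    by_beta = dict(fits)
    chosen = fallback_beta
    if chosen not in by_beta:
        chosen = window[-1] if chosen > window[-1] else window[0]
    logger.info("%s: no beta in [%d, %d] reached R2 %.2f, using default %d",
                net.subtype, window[0], window[-1], r2_target, chosen)
    return float(chosen), float(by_beta[chosen])


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), diag 1."""
    a = np.asarray(adjacency, float)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    net: AggregatedNetwork,
    beta: float,
    min_module_size: int = 10,
    cut_height: float = 0.95,
    kin_ratio: float = 0.85,
) -> ModulePartition:
    """Cluster the weighted network into modules; leftovers to Module0.

    Average-linkage clustering on 1 - TOM, static cut at ``cut_height``,
    followed by two membership cleanups per cluster. First, genes whose
    mean dissimilarity to the rest of their cluster exceeds the cut
    height are peeled off iteratively — a static cut bounds a cluster's
    merge height, not each member's fit. Second, genes whose
    intramodular connectivity (mean |cor| to cluster peers) falls more
    than ``1 - kin_ratio`` below the cluster median are removed in one
    pass: such genes ride into a module through a few strong
    (often borderline-significant) edges amplified by shared-neighbour
    topological overlap, while genuine members are comparably
    correlated with the whole module. Clusters then smaller than
    ``min_module_size`` are merged into Module0 and surviving modules
    renumbered 1..Sn by decreasing size (ties by first gene id).
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    genes = list(net.genes)
    if len(genes) < min_module_size:
        logger.warning("%s: %d genes < min module size, all to Module0",
                       net.subtype, len(genes))
        return ModulePartition(net.subtype, {g: 0 for g in genes}, beta, np.nan)
    a = np.power(_masked_abs_cor(net), beta)
    dissim = 1.0 - topological_overlap(a)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    pos = {g: i for i, g in enumerate(genes)}
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    abs_cor = np.abs(net.cor)
    for c, members in clusters.items():
        kept = _peel_stragglers(members, pos, dissim, cut_height)
        clusters[c] = _peel_low_connectivity(kept, pos, abs_cor, kin_ratio)
    big = [gs for gs in clusters.values() if len(gs) >= min_module_size]
    big.sort(key=lambda gs: (-len(gs), min(gs)))
    assignment = {g: 0 for g in genes}
    for i, gs in enumerate(big, start=1):
        for g in gs:
            assignment[g] = i
    return ModulePartition(net.subtype, assignment, float(beta), float(np.nan))


def _peel_stragglers(
    members: list, pos: dict, dissim: np.ndarray, cut_height: float
) -> list:
    """Iteratively drop genes whose mean in-cluster dissim > cut_height."""
    current = list(members)
    while len(current) > 1:
        idx = np.array([pos[g] for g in current])
        sub = dissim[np.ix_(idx, idx)]
        mean_d = sub.sum(axis=1) / (len(current) - 1)
        bad = mean_d > cut_height
        if not bad.any():
            break
        worst = int(np.argmax(mean_d))
        current.pop(worst)
    return current


def _peel_low_connectivity(
    members: list, pos: dict, abs_cor: np.ndarray, kin_ratio: float
) -> list:
    """Single-pass removal of genes with atypically low mean |cor|.

    Connectivity is compared to the cluster median, so uniformly weak
    but coherent modules are untouched.
    """
    if len(members) < 3:
        return list(members)
    idx = np.array([pos[g] for g in members])
    sub = abs_cor[np.ix_(idx, idx)]
    kin = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
    threshold = kin_ratio * np.median(kin)
    return [g for g, k in zip(members, kin) if k >= threshold]


def fit_partition(
    net: AggregatedNetwork,
    candidates=None,
    min_module_size: int = 10,
    cut_height: float = 0.95,
) -> ModulePartition:
    """Convenience: soft-threshold pick followed by module detection."""
    beta, r2 = pick_soft_threshold(
        net, candidates=candidates, adjacency_floor=1.0 - cut_height
    )
    part = detect_modules(net, beta, min_module_size, cut_height)
    part.r2 = r2
    return part
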