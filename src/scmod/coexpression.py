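"""Subsampling-averaged Spearman co-expression networks.

A subtype's network ("MeanNet") is built by drawing F subsamples of Ns
samples, computing pairwise Spearman correlations and p-values on each,
then combining folds: correlations by arithmetic mean, p-values by
geometric mean. Edges with combined p above alpha are discarded, and
genes left without any significant edge are removed.

Subsampling with a shared fold size Ns makes correlation estimates
comparable across subtypes of very different sizes, which is the point:
raw Spearman significance depends strongly on sample count.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionDataset

logger = logging.getLogger(__name__)

MAX_FOLD_SIZE = 50  # default cap on Ns; beyond this Spearman is stable enough


@dataclass(frozen=True)
class SubsampleScheme:
    """Fold plan for one aggregation run: F folds of Ns samples each."""

    F: int
    Ns: int
    seed: int = 0

    def __post_init__(self):
        if self.F < 1 or self.Ns < 1:
            raise ValueError("F and Ns must be positive")


def default_scheme(ds: ExpressionDataset, subtype: str, seed: int = 0) -> SubsampleScheme:
    """Scheme with Ns = min subtype size - 1 (capped) and F = ceil(3n/Ns).

    F is sized so every sample of the subtype is expected to be drawn
    well before the coverage repair in :func:`make_folds` kicks in.
    """
    sizes = ds.labels.value_counts()
    ns = min(int(sizes.min()) - 1, MAX_FOLD_SIZE)
    ns = max(ns, 3)
    n = int(sizes[subtype])
    f = math.ceil(3 * n / ns)
    return SubsampleScheme(F=f, Ns=ns, seed=seed)


@dataclass
class AggregatedNetwork:
    """Per-subtype aggregated network: mean cor, combined p, edge mask.

    ``significant`` stays None until :func:`prune` sets it; after
    pruning every retained gene has at least one significant edge.
    """

    subtype: str
    genes: list
    cor: np.ndarray
    pval: np.ndarray
    n_folds: int
    significant: np.ndarray | None = None

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    def gene_index(self, gene) -> int | None:
        return self._index.get(gene)

    def edge(self, a, b) -> tuple[float, float] | None:
        """(cor, pval) for a gene pair, or None if a gene is absent."""
        i, j = self._index.get(a), self._index.get(b)
        if i is None or j is None:
            return None
        return float(self.cor[i, j]), float(self.pval[i, j])

    def is_significant(self, a, b) -> bool:
        if self.significant is None:
            return False
        i, j = self._index.get(a), self._index.get(b)
        if i is None or j is None:
            return False
        return bool(self.significant[i, j])


def make_folds(sample_ids: list, scheme: SubsampleScheme) -> list[list]:
    """Draw F folds of Ns ids without replacement (within a fold).

    Folds are drawn independently; if some sample is never selected the
    last folds are repaired by swapping in unseen samples in place of
    samples that occur in more than one fold. Deterministic given seed.
    """
    ids = list(sample_ids)
    n = len(ids)
    if scheme.Ns > n:
        raise ValueError(f"fold size Ns={scheme.Ns} exceeds {n} samples")
    rng = np.random.default_rng(scheme.seed)
    folds = [list(rng.choice(ids, size=scheme.Ns, replace=False)) for _ in range(scheme.F)]

    counts: dict = {s: 0 for s in ids}
    for fold in folds:
        for s in fold:
            counts[s] += 1
    unseen = [s for s in ids if counts[s] == 0]
    if unseen and scheme.F * scheme.Ns < n:
        raise ValueError("F*Ns smaller than the subtype size: coverage impossible")
    fi, pos = len(folds) - 1, 0
    for s in unseen:
        placed = False
        while not placed:
            fold = folds[fi]
            while pos < len(fold):
                victim = fold[pos]
                if counts[victim] > 1 and s not in fold:
                    counts[victim] -= 1
                    fold[pos] = s
                    counts[s] = 1
                    placed = True
                    pos += 1
                    break
                pos += 1
            if not placed:
                fi -= 1
                pos = 0
                if fi < 0:
                    raise RuntimeError("fold coverage repair failed")
    return folds


def _spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-then-Pearson Spearman matrix with t-approximation p-values."""
    n, m = X.shape
    ranks = stats.rankdata(X, axis=0)
    sd = ranks.std(axis=0)
    safe = ranks.copy()
    safe[:, sd == 0] = np.nan  # constant genes: leave nan, caller zeroes
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(safe, rowvar=False)
        rho = np.atleast_2d(rho)
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return rho, p


def spearman_network(
    ds: ExpressionDataset, sample_subset: list
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p over a sample subset.

    Ties get average ranks; p-values use the t approximation. A gene
    constant on the subset gets rho 0 / p 1 against everything.
    """
    if len(sample_subset) < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    X = ds.values[list(sample_subset)].to_numpy().T  # samples x genes
    n_genes = X.shape[1]
    with np.errstate(invalid="ignore"):
        rho, p = stats.spearmanr(X, axis=0)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if rho.shape != (n_genes, n_genes):
        # spearmanr collapses to a scalar for 2 genes and bails out
        # entirely when any gene is constant; recompute by hand
        rho, p = _spearman_matrix(X)
    const = X.std(axis=0) == 0
    if const.any():
        logger.warning("%d genes constant on subset; correlations set to 0", const.sum())
    bad = np.isnan(rho)
    rho[bad] = 0.0
    p[bad] = 1.0
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    p[const, :] = 1.0
    p[:, const] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return rho, p


def aggregate(
    ds: ExpressionDataset, subtype: str, scheme: SubsampleScheme | None = None
) -> AggregatedNetwork:
    """Build the subtype MeanNet: fold-mean cor, geometric-mean p.

    Correlations are averaged as signed values. Fold p-values of 0 are
    clamped to machine epsilon before the geometric mean so a single
    saturated fold cannot annihilate the combined score.
    """
    samples = ds.samples_of(subtype)
    if scheme is None:
        scheme = default_scheme(ds, subtype)
    folds = make_folds(samples, scheme)
    cor_sum = np.zeros((ds.n_genes, ds.n_genes))
    logp_sum = np.zeros_like(cor_sum)
    eps = np.finfo(float).eps
    for fold in folds:
        rho, p = spearman_network(ds, fold)
        cor_sum += rho
        logp_sum += np.log(np.maximum(p, eps))
    cor = cor_sum / len(folds)
    pval = np.exp(logp_sum / len(folds))
    np.fill_diagonal(cor, 1.0)
    np.fill_diagonal(pval, 0.0)
    return AggregatedNetwork(
        subtype=subtype, genes=ds.gene_ids, cor=cor, pval=pval, n_folds=len(folds)
    )


def prune(net: AggregatedNetwork, alpha: float = 0.01) -> AggregatedNetwork:
    """Mark edges with combined p <= alpha and drop isolated genes."""
    if not (0 < alpha < 1) and alpha != 1:
        raise ValueError("alpha must be in (0, 1]")
    sig = net.pval <= alpha
    np.fill_diagonal(sig, False)
    keep = sig.any(axis=1)
    if not keep.any():
        raise ValueError(f"{net.subtype}: no significant edges at alpha={alpha}")
    idx = np.where(keep)[0]
    return AggregatedNetwork(
        subtype=net.subtype,
        genes=[net.genes[i] for i in idx],
        cor=net.cor[np.ix_(idx, idx)],
        pval=net.pval[np.ix_(idx, idx)],
        n_folds=net.n_folds,
        significant=sig[np.ix_(idx, idx)],
    )


def save_network(net: AggregatedNetwork, path, sidecar: dict | None = None) -> None:
    """Write the upper-triangle edge list as TSV plus a JSON sidecar."""
    n = len(net.genes)
    iu = np.triu_indices(n, k=1)
    sig = net.significant if net.significant is not None else np.zeros((n, n), bool)
    df = pd.DataFrame(
        {
            "gene_a": [net.genes[i] for i in iu[0]],
            "gene_b": [net.genes[j] for j in iu[1]],
            "cor": net.cor[iu],
            "pval": net.pval[iu],
            "significant": sig[iu].astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {"subtype": net.subtype, "n_folds": net.n_folds, "n_genes": n}
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_network(path) -> AggregatedNetwork:
    df = pd.read_csv(path, sep="\t")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    cor = np.eye(n)
    pval = np.zeros((n, n))
    sig = np.zeros((n, n), bool)
    ia = df["gene_a"].map(idx).to_numpy()
    ib = df["gene_b"].map(idx).to_numpy()
    cor[ia, ib] = cor[ib, ia] = df["cor"]
    pval[ia, ib] = pval[ib, ia] = df["pval"]
    sig[ia, ib] = sig[ib, ia] = df["significant"].astype(bool)
    return AggregatedNetwork(
        subtype=meta["subtype"], genes=genes, cor=cor, pval=pval,
        n_folds=meta["n_folds"], significant=sig,
    )
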