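"""Single-sample network-perturbation features.

Each reference network set holds, for every subtype, the Spearman
correlations at that subtype's specific edges computed from P randomly
drawn *training* samples of that subtype. A query sample is featurized
by appending it to each subtype's P reference samples, recomputing the
correlations at the specific edges, and recording the absolute shift
|cor' - cor| per edge. The T blocks of E shifts are concatenated into
one length-T*E vector.

The intuition: a sample of subtype x barely perturbs x's own specific
edges (it follows the same co-expression pattern) but disturbs other
subtypes' specific edges noticeably. Drawing several reference sets
both augments scarce subtypes for training and enables vote-based
prediction at test time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import ExpressionDataset
from .specificity import SpecificEdgeSet

logger = logging.getLogger(__name__)

MAX_REFERENCE_SIZE = 30  # default cap on P


def spearman_pairs(values: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Spearman rho for selected row pairs of a genes x samples matrix.

    Rank-transform each row (average ranks on ties), then Pearson on
    ranks per pair. Constant rows give rho 0.
    """
    r = rankdata(values, axis=1)
    rc = r - r.mean(axis=1, keepdims=True)
    num = (rc[ia] * rc[ib]).sum(axis=1)
    den = np.sqrt((rc[ia] ** 2).sum(axis=1) * (rc[ib] ** 2).sum(axis=1))
    out = np.zeros(len(ia))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclass
class _SubtypeReference:
    """One subtype's slice of a reference set, pre-indexed for speed."""

    genes: list
    gene_pos: dict
    ia: np.ndarray
    ib: np.ndarray
    sample_ids: list
    values: np.ndarray  # genes x P
    cor: np.ndarray  # length E


@dataclass
class ReferenceNetworkSet:
    """T per-subtype reference correlations at the specific edges."""

    set_id: int
    refs: dict  # subtype -> _SubtypeReference

    @property
    def subtypes(self) -> list:
        return sorted(self.refs)

    def reference_samples(self, subtype: str) -> list:
        return list(self.refs[subtype].sample_ids)

    def reference_cor(self, subtype: str) -> np.ndarray:
        return self.refs[subtype].cor


def split_train_test(
    ds: ExpressionDataset, test_fraction: float = 0.1, seed: int = 0
) -> tuple[list, list]:
    """Stratified split: round(f*n) per subtype (min 1 when f > 0) to test."""
    if not (0 <= test_fraction < 1):
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for subtype in ds.subtypes:
        ids = ds.samples_of(subtype)
        if len(ids) < 2:
            raise ValueError(f"{subtype}: need >= 2 samples to split")
        n_test = int(round(test_fraction * len(ids)))
        if test_fraction > 0:
            n_test = min(max(n_test, 1), len(ids) - 1)
        perm = list(rng.permutation(ids))
        test.extend(perm[:n_test])
        train.extend(perm[n_test:])
    return sorted(train), sorted(test)


def _edge_index(edge_set: SpecificEdgeSet) -> tuple[list, dict, np.ndarray, np.ndarray]:
    genes = sorted({g for pair in edge_set.pairs for g in pair})
    pos = {g: i for i, g in enumerate(genes)}
    ia = np.array([pos[a] for a, _ in edge_set.pairs])
    ib = np.array([pos[b] for _, b in edge_set.pairs])
    return genes, pos, ia, ib


def default_reference_size(ds: ExpressionDataset, train_ids: list) -> int:
    labels = ds.labels.loc[train_ids]
    return min(int(labels.value_counts().min()) - 1, MAX_REFERENCE_SIZE)


def build_reference_sets(
    ds: ExpressionDataset,
    train_ids: list,
    edge_sets: dict,
    P: int | None = None,
    n_sets: int = 10,
    seed: int = 0,
) -> list[ReferenceNetworkSet]:
    """Draw n_sets reference network sets of P training samples per subtype."""
    labels = ds.labels.loc[train_ids]
    if P is None:
        P = default_reference_size(ds, train_ids)
    if P < 3:
        raise ValueError("P must be >= 3")
    sizes = labels.value_counts()
    if P > sizes.min():
        raise ValueError(
            f"P={P} exceeds smallest training subtype ({int(sizes.min())})"
        )
    rng = np.random.default_rng(seed)
    by_subtype = {s: sorted(labels.index[labels == s]) for s in ds.subtypes}
    indexed = {s: _edge_index(edge_sets[s]) for s in ds.subtypes}
    sets = []
    for set_id in range(n_sets):
        refs = {}
        for s in ds.subtypes:
            chosen = sorted(rng.choice(by_subtype[s], size=P, replace=False))
            genes, pos, ia, ib = indexed[s]
            vals = ds.values.loc[genes, chosen].to_numpy()
            refs[s] = _SubtypeReference(
                genes=genes, gene_pos=pos, ia=ia, ib=ib,
                sample_ids=chosen, values=vals,
                cor=spearman_pairs(vals, ia, ib),
            )
        sets.append(ReferenceNetworkSet(set_id=set_id, refs=refs))
    return sets


def feature_names(edge_sets: dict) -> list[str]:
    names = []
    for s in sorted(edge_sets):
        for a, b in edge_sets[s].pairs:
            names.append(f"{s}__{a}__{b}")
    return names


def perturb(
    sample_values: pd.Series, ref: ReferenceNetworkSet, sample_id: str | None = None
) -> np.ndarray:
    """Length-T*E perturbation vector of one sample against one set.

    Per subtype block: |Spearman at the specific edges over the P
    reference samples plus this sample, minus the reference value|.

    When the sample itself is one of the P reference samples (it can
    be, for training samples), the perturbation is measured
    leave-one-out: the network without the sample is the reference and
    the full draw is the expanded network. Otherwise a sample would
    perturb a network it already belongs to, which systematically
    understates its own-subtype perturbation relative to unseen
    samples.
    """
    blocks = []
    for s in ref.subtypes:
        sub = ref.refs[s]
        if sample_id is not None and sample_id in sub.sample_ids:
            pos = sub.sample_ids.index(sample_id)
            without = np.delete(sub.values, pos, axis=1)
            cor_base = spearman_pairs(without, sub.ia, sub.ib)
            blocks.append(np.abs(sub.cor - cor_base))
            continue
        try:
            col = sample_values.loc[sub.genes].to_numpy()
        except KeyError as exc:
            raise ValueError(f"sample missing specific-module genes of {s}") from exc
        expanded = np.column_stack([sub.values, col])
        cor_prime = spearman_pairs(expanded, sub.ia, sub.ib)
        blocks.append(np.abs(cor_prime - sub.cor))
    return np.concatenate(blocks)


def _pairing_counts(n_samples: int, balance_to: int, n_sets: int, subtype: str) -> int:
    reps = math.ceil(balance_to / n_samples)
    if reps > n_sets:
        logger.warning(
            "%s: balance target %d needs %d sets/sample but only %d available",
            subtype, balance_to, reps, n_sets,
        )
        reps = n_sets
    return reps


def featurize_training(
    ds: ExpressionDataset,
    train_ids: list,
    ref_sets: list,
    edge_sets: dict,
    balance_to: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled feature matrix with per-subtype augmentation balancing.

    Each training sample is paired with enough reference sets (seeded
    round-robin) that every subtype contributes about ``balance_to``
    vectors (default: size of the largest training subtype). Rows are
    indexed by (sample_id, set_id); the last column is the label.
    """
    if not ref_sets:
        raise ValueError("no reference sets")
    labels = ds.labels.loc[train_ids]
    sizes = labels.value_counts()
    if balance_to is None:
        balance_to = int(sizes.max())
    n_sets = len(ref_sets)
    rng = np.random.default_rng(seed)
    names = feature_names(edge_sets)
    rows, index, y = [], [], []
    for s in ds.subtypes:
        ids = sorted(labels.index[labels == s])
        reps = _pairing_counts(len(ids), balance_to, n_sets, s)
        ids = list(rng.permutation(ids))
        cursor = 0
        for sid in ids:
            sample = ds.values[sid]
            for _ in range(reps):
                ref = ref_sets[cursor % n_sets]
                rows.append(perturb(sample, ref, sample_id=sid))
                index.append((sid, ref.set_id))
                y.append(s)
                cursor += 1
    df = pd.DataFrame(
        rows, columns=names,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "set_id"]),
    )
    df["label"] = y
    return df.sort_index()


def featurize_samples(
    ds: ExpressionDataset, sample_ids: list, ref_sets: list, edge_sets: dict,
    with_labels: bool = True,
) -> pd.DataFrame:
    """Featurize samples against *all* reference sets (for voting)."""
    names = feature_names(edge_sets)
    rows, index = [], []
    for sid in sample_ids:
        sample = ds.values[sid]
        for ref in ref_sets:
            rows.append(perturb(sample, ref, sample_id=sid))
            index.append((sid, ref.set_id))
    df = pd.DataFrame(
        rows, columns=names,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "set_id"]),
    )
    if with_labels:
        df["label"] = [ds.labels[sid] for sid, _ in index]
    return df


def audit_no_leak(ref_sets: list, test_ids: list) -> None:
    """Raise if any test sample id appears inside any reference set."""
    test = set(test_ids)
    for ref in ref_sets:
        for s in ref.subtypes:
            leaked = test & set(ref.reference_samples(s))
            if leaked:
                raise AssertionError(f"test samples leaked into references: {leaked}")
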