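"""Specific co-expression module and specific-edge selection.

A subtype's specific module is the module whose genes co-cluster
nowhere else (score 1, ranked by maximum cross-subtype overlap ratio)
and whose edges are much stronger there than in any other subtype
(score 2, ranked by the worst-case edge-mean gap). The two ranks are
summed and the minimum wins. Inside that module, the top-E edges by
the signed correlation margin over all other subtypes are the
subtype's specific edges — the coordinates every downstream
perturbation feature is measured at.

Module0 (the unclustered residual bin) never participates: neither as
a source module nor as a co-clustering target. Edges absent from
another subtype's network — not significant there, or a gene pruned
away — contribute correlation 0 in that subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import AggregatedNetwork
from .module_detection import ModulePartition

logger = logging.getLogger(__name__)


@dataclass
class ModuleSpecificityTable:
    """Per-module specificity scores for one subtype.

    ``table`` is indexed by module number with columns
    max_overlap_ratio, score1, min_mean_gap, score2, total.
    """

    subtype: str
    table: pd.DataFrame


@dataclass
class SpecificEdgeSet:
    """Top-E specific edges of one subtype, sorted by delta descending.

    ``edges`` columns: gene_a, gene_b, delta, and one ``cor_<subtype>``
    column per subtype (0 where the pair is absent there).
    """

    subtype: str
    module: int
    module_genes: set
    edges: pd.DataFrame

    @property
    def pairs(self) -> list[tuple]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def __len__(self) -> int:
        return len(self.edges)


def overlap_ratio(source_module: set, target_module: set) -> float:
    """|source ∩ target| / |source|."""
    source = set(source_module)
    if not source:
        raise ValueError("empty source module")
    return len(source & set(target_module)) / len(source)


def _ranks(values: dict, *, descending: bool) -> dict:
    """Competition-free ranks 1..n; ties broken by module index."""
    sign = -1 if descending else 1
    order = sorted(values, key=lambda m: (sign * values[m], m))
    return {m: r for r, m in enumerate(order, start=1)}


def score1(partitions: dict, s: str) -> tuple[dict, dict]:
    """Max cross-subtype overlap ratio per module of s, ranked ascending.

    Returns (max_overlap_ratio per module, rank per module). Module0 of
    target subtypes is skipped; a module whose genes land only in other
    subtypes' Module0 scores overlap 0 and ranks first.
    """
    part_s = partitions[s]
    mods = part_s.modules()
    if not mods:
        raise ValueError(f"{s}: no non-trivial modules")
    ratios = {}
    for i in mods:
        genes_i = part_s.module_genes(i)
        best = 0.0
        for t, part_t in partitions.items():
            if t == s:
                continue
            for j in part_t.modules():
                best = max(best, overlap_ratio(genes_i, part_t.module_genes(j)))
        ratios[i] = best
    return ratios, _ranks(ratios, descending=False)


def _module_edges(net: AggregatedNetwork, genes: set) -> list[tuple]:
    """Significant (gene_a, gene_b, cor) pairs of ``net`` within ``genes``."""
    idx = [net.gene_index(g) for g in sorted(genes)]
    present = [(g, i) for g, i in zip(sorted(genes), idx) if i is not None]
    out = []
    for a_pos in range(len(present)):
        ga, ia = present[a_pos]
        for b_pos in range(a_pos + 1, len(present)):
            gb, ib = present[b_pos]
            if net.significant[ia, ib]:
                out.append((ga, gb, float(net.cor[ia, ib])))
    return out


def edge_cor_in(net: AggregatedNetwork, a, b) -> float:
    """Signed correlation of pair (a, b) in ``net``, 0 if absent there."""
    if not net.is_significant(a, b):
        return 0.0
    return net.edge(a, b)[0]


def score2(partitions: dict, networks: dict, s: str) -> tuple[dict, dict]:
    """Worst-case edge-mean gap per module of s, ranked descending.

    For module M: edgemean_s is the mean signed correlation over its
    significant edges in s; for each other subtype t the same pairs are
    averaged with 0 substituted for absent edges; the gap is the
    minimum of edgemean_s - edgemean_t over t. Modules with no edges
    are excluded with a warning.
    """
    part_s = partitions[s]
    net_s = networks[s]
    gaps = {}
    for i in part_s.modules():
        edges = _module_edges(net_s, part_s.module_genes(i))
        if not edges:
            logger.warning("%s module %d has no significant edges; excluded", s, i)
            continue
        mean_s = float(np.mean([c for _, _, c in edges]))
        worst = np.inf
        for t, net_t in networks.items():
            if t == s:
                continue
            mean_t = float(np.mean([edge_cor_in(net_t, a, b) for a, b, _ in edges]))
            worst = min(worst, mean_s - mean_t)
        gaps[i] = worst
    if not gaps:
        raise ValueError(f"{s}: every module lacks edges")
    return gaps, _ranks(gaps, descending=True)


def specificity_table(partitions: dict, networks: dict, s: str) -> ModuleSpecificityTable:
    ratios, r1 = score1(partitions, s)
    gaps, r2 = score2(partitions, networks, s)
    mods = sorted(set(r1) & set(r2))
    table = pd.DataFrame(
        {
            "max_overlap_ratio": [ratios[m] for m in mods],
            "score1": [r1[m] for m in mods],
            "min_mean_gap": [gaps[m] for m in mods],
            "score2": [r2[m] for m in mods],
        },
        index=pd.Index(mods, name="module"),
    )
    table["total"] = table["score1"] + table["score2"]
    return ModuleSpecificityTable(subtype=s, table=table)


def select_specific_module(table: ModuleSpecificityTable) -> int:
    """Module with minimal total rank; ties by score2 then module index."""
    t = table.table
    if t.empty:
        raise ValueError(f"{table.subtype}: empty specificity table")
    order = sorted(t.index, key=lambda m: (t.at[m, "total"], t.at[m, "score2"], m))
    return int(order[0])


def select_specific_edges(
    module_genes: set, networks: dict, s: str, E: int = 100
) -> SpecificEdgeSet:
    """Top-E significant in-module edges of s by margin over other subtypes.

    delta = cor_s - max over other subtypes of (signed cor, 0 if the
    pair is absent there). Ties broken lexicographically by gene ids.
    """
    if E < 1:
        raise ValueError("E must be >= 1")
    net_s = networks[s]
    others = [t for t in networks if t != s]
    rows = []
    for a, b, cor_s in _module_edges(net_s, module_genes):
        cors = {t: edge_cor_in(networks[t], a, b) for t in others}
        delta = cor_s - max(cors.values())
        row = {"gene_a": a, "gene_b": b, "delta": delta, f"cor_{s}": cor_s}
        row.update({f"cor_{t}": cors[t] for t in others})
        rows.append(row)
    if len(rows) < E:
        raise ValueError(
            f"{s}: specific module has only {len(rows)} candidate edges, need E={E}"
        )
    df = pd.DataFrame(rows).sort_values(
        ["delta", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    df = df.head(E).reset_index(drop=True)
    cols = ["gene_a", "gene_b", "delta"] + [f"cor_{t}" for t in sorted(networks)]
    module = -1  # caller may set; kept for serialization only
    return SpecificEdgeSet(
        subtype=s, module=module, module_genes=set(module_genes), edges=df[cols]
    )


def find_specific_edges(
    partitions: dict, networks: dict, E: int = 100
) -> dict[str, SpecificEdgeSet]:
    """Full per-subtype selection: table -> specific module -> top-E edges."""
    out = {}
    for s in sorted(networks):
        table = specificity_table(partitions, networks, s)
        mod = select_specific_module(table)
        edge_set = select_specific_edges(
            partitions[s].module_genes(mod), networks, s, E=E
        )
        edge_set.module = mod
        out[s] = edge_set
    return out
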