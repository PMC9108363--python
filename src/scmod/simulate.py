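"""Synthetic expression data with planted subtype-specific modules.

The generator emulates the structure the pipeline is built to detect:
T subtype groups of imbalanced size; one gene block per subtype that is
strongly co-expressed only within that subtype (a single latent factor
per sample drives the block); optional shared background blocks
co-expressed in every subtype; and independent noise genes. Values sit
on a log-like scale around ``baseline`` and are clipped at zero.

Within a planted block the population Pearson correlation is
load^2 / (load^2 + noise_sd^2); Spearman on the Gaussian generator is
slightly lower (2/pi * arcsin of it). Outside its own subtype a block
gene is pure unit-variance noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExpressionDataset


@dataclass(frozen=True)
class SimulationSpec:
    """Generator conditions; defaults echo an imbalanced 4-subtype study."""

    T: int = 4
    sizes: tuple = (20, 60, 12, 25)
    n_genes: int = 300
    module_size: int = 25
    n_shared_modules: int = 1
    shared_size: int = 30
    within_load: float = 0.9
    noise_sd: float = 0.3
    noise_gene_sd: float = 0.6
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if len(self.sizes) != self.T:
            raise ValueError("sizes must have T entries")
        if any(n < 5 for n in self.sizes):
            raise ValueError("every subtype needs >= 5 samples")
        planted = self.T * self.module_size + self.n_shared_modules * self.shared_size
        if planted > self.n_genes:
            raise ValueError("planted blocks exceed the gene count")
        if not (0 < self.within_load < 1):
            raise ValueError("within_load must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted gene sets: one specific block per subtype, shared blocks."""

    specific: dict  # subtype -> set of gene ids
    shared: list  # list of sets

    def all_blocks(self) -> dict:
        out = {f"specific:{s}": g for s, g in self.specific.items()}
        out.update({f"shared:{i}": g for i, g in enumerate(self.shared)})
        return out


def subtype_names(T: int) -> list[str]:
    return [f"grp{i + 1:02d}" for i in range(T)]


def simulate(spec: SimulationSpec | None = None) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a seeded dataset and its ground truth."""
    if spec is None:
        spec = SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    names = subtype_names(spec.T)
    sample_ids, labels = [], []
    for name, n in zip(names, spec.sizes):
        for j in range(n):
            sample_ids.append(f"{name}_s{j + 1:03d}")
            labels.append(name)
    n_total = len(sample_ids)
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]

    # unstructured genes: flat profiles with sub-unit spread, so the
    # variability filter ranks them below co-regulated genes as it
    # would on real data; block genes outside their own subtype keep a
    # unit spread (they are expressed, just not co-regulated there)
    values = spec.baseline + spec.noise_gene_sd * rng.standard_normal(
        (spec.n_genes, n_total)
    )

    col_of = {}
    start = 0
    for name, n in zip(names, spec.sizes):
        col_of[name] = np.arange(start, start + n)
        start += n

    truth_specific, truth_shared = {}, []
    g0 = 0
    for name, n in zip(names, spec.sizes):
        rows = slice(g0, g0 + spec.module_size)
        cols = col_of[name]
        z = rng.standard_normal(len(cols))
        eps = rng.standard_normal((spec.module_size, len(cols)))
        values[rows, cols[0]:cols[-1] + 1] = (
            spec.baseline + spec.within_load * z + spec.noise_sd * eps
        )
        other = np.setdiff1d(np.arange(n_total), cols)
        values[rows, :][:, other] = spec.baseline + rng.standard_normal(
            (spec.module_size, len(other))
        )
        truth_specific[name] = set(genes[g0:g0 + spec.module_size])
        g0 += spec.module_size
    for _ in range(spec.n_shared_modules):
        rows = slice(g0, g0 + spec.shared_size)
        z = rng.standard_normal(n_total)
        eps = rng.standard_normal((spec.shared_size, n_total))
        values[rows, :] = spec.baseline + spec.within_load * z + spec.noise_sd * eps
        truth_shared.append(set(genes[g0:g0 + spec.shared_size]))
        g0 += spec.shared_size

    values = np.clip(values, 0.0, None)
    ds = ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        labels=pd.Series(labels, index=sample_ids, name="subtype"),
        log_transformed=False,
    )
    return ds, GroundTruth(specific=truth_specific, shared=truth_shared)
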