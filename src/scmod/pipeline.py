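"""End-to-end orchestration: expression matrix in, subtype calls out.

Stages: preprocess -> per-subtype aggregated networks -> module
detection -> specific module / edge selection -> train-test split ->
reference network sets -> perturbation features -> MLP training ->
vote-aggregated prediction -> evaluation. Every stage draws its seed
deterministically from the master seed, so a stage can be rerun in
isolation and a rerun of the whole pipeline reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classifier as clf
from . import coexpression as coexpr
from . import features as feat
from . import module_detection as moddet
from . import specificity as spec_mod
from .classifier import ClassifierConfig, EvaluationReport
from .coexpression import SubsampleScheme
from .preprocess import ExpressionDataset, filter_genes, load_expression

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths."""

    matrix_path: str | None = None
    labels_path: str | None = None
    outdir: str | None = None
    log_transform: bool = True
    min_mean: float = 10.0
    keep_fraction: float = 0.9
    Ns: int | None = None
    F: int | None = None
    alpha: float = 0.01
    min_module_size: int = 10
    cut_height: float = 0.95
    E: int = 100
    P: int | None = None
    n_sets: int = 10
    test_fraction: float = 0.1
    balance_to: int | None = None
    hidden_sizes: tuple = (50, 10)
    learning_rate: float = 0.1
    batch_size: int = 32
    max_epochs: int = 500
    early_stop_patience: int = 20
    validation_fraction: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hidden_sizes" in raw:
            raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            validation_fraction=self.validation_fraction,
            seed=stage_seed(self.seed, "train"),
        )


@dataclass
class PipelineResult:
    dataset: ExpressionDataset
    networks: dict
    partitions: dict
    tables: dict
    edge_sets: dict
    train_ids: list
    test_ids: list
    reference_sets: list
    model: clf.SubtypeClassifier
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    predictions: pd.DataFrame
    report: EvaluationReport


def _sidecar(path: Path, payload: dict) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def build_networks(ds: ExpressionDataset, cfg: PipelineConfig) -> dict:
    """Aggregated + pruned network per subtype."""
    nets = {}
    for s in ds.subtypes:
        if cfg.Ns is not None:
            f = cfg.F
            if f is None:
                f = math.ceil(3 * len(ds.samples_of(s)) / cfg.Ns)
            scheme = SubsampleScheme(F=f, Ns=cfg.Ns, seed=stage_seed(cfg.seed, f"net:{s}"))
        else:
            scheme = coexpr.default_scheme(ds, s, seed=stage_seed(cfg.seed, f"net:{s}"))
        net = coexpr.aggregate(ds, s, scheme)
        nets[s] = coexpr.prune(net, alpha=cfg.alpha)
        logger.info("%s: %d genes retained after pruning", s, len(nets[s].genes))
    return nets


def detect_all_modules(networks: dict, cfg: PipelineConfig) -> dict:
    return {
        s: moddet.fit_partition(
            net, min_module_size=cfg.min_module_size, cut_height=cfg.cut_height
        )
        for s, net in networks.items()
    }


def run_pipeline(cfg: PipelineConfig, ds: ExpressionDataset | None = None) -> PipelineResult:
    """Run the full workflow; writes artifacts when cfg.outdir is set."""
    if ds is None:
        if cfg.matrix_path is None or cfg.labels_path is None:
            raise ValueError("need either a dataset or matrix/labels paths")
        ds = load_expression(cfg.matrix_path, cfg.labels_path, cfg.log_transform)
    try:
        ds = filter_genes(ds, min_mean=cfg.min_mean, keep_fraction=cfg.keep_fraction)
    except ValueError as exc:
        raise RuntimeError(f"stage preprocess failed: {exc}") from exc

    try:
        networks = build_networks(ds, cfg)
    except ValueError as exc:
        raise RuntimeError(f"stage networks failed: {exc}") from exc
    try:
        partitions = detect_all_modules(networks, cfg)
    except ValueError as exc:
        raise RuntimeError(f"stage modules failed: {exc}") from exc

    try:
        tables = {
            s: spec_mod.specificity_table(partitions, networks, s) for s in networks
        }
        edge_sets = {}
        for s in sorted(networks):
            mod = spec_mod.select_specific_module(tables[s])
            es = spec_mod.select_specific_edges(
                partitions[s].module_genes(mod), networks, s, E=cfg.E
            )
            es.module = mod
            edge_sets[s] = es
    except ValueError as exc:
        raise RuntimeError(f"stage specificity failed: {exc}") from exc

    train_ids, test_ids = feat.split_train_test(
        ds, cfg.test_fraction, seed=stage_seed(cfg.seed, "split")
    )
    try:
        ref_sets = feat.build_reference_sets(
            ds, train_ids, edge_sets, P=cfg.P, n_sets=cfg.n_sets,
            seed=stage_seed(cfg.seed, "references"),
        )
    except ValueError as exc:
        raise RuntimeError(f"stage references failed: {exc}") from exc
    feat.audit_no_leak(ref_sets, test_ids)

    train_df = feat.featurize_training(
        ds, train_ids, ref_sets, edge_sets, balance_to=cfg.balance_to,
        seed=stage_seed(cfg.seed, "featurize"),
    )
    model = clf.train(train_df, cfg.classifier_config())

    if test_ids:
        test_df = feat.featurize_samples(ds, test_ids, ref_sets, edge_sets)
        predictions = clf.predict_samples(model, test_df)
        y_true = [ds.labels[s] for s in predictions.index]
        report = clf.evaluate(y_true, predictions["predicted"], classes=ds.subtypes)
    else:
        test_df = pd.DataFrame()
        predictions = pd.DataFrame(columns=["predicted", "n_votes_for_winner"])
        report = None

    result = PipelineResult(
        dataset=ds, networks=networks, partitions=partitions, tables=tables,
        edge_sets=edge_sets, train_ids=train_ids, test_ids=test_ids,
        reference_sets=ref_sets, model=model, train_features=train_df,
        test_features=test_df, predictions=predictions, report=report,
    )
    if cfg.outdir:
        write_artifacts(result, cfg)
    return result


def write_artifacts(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)

    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    for s, net in result.networks.items():
        coexpr.save_network(
            net, nets_dir / f"{s}.tsv",
            sidecar={"alpha": cfg.alpha, "seed": stage_seed(cfg.seed, f"net:{s}")},
        )
    mods_dir = out / "modules"
    mods_dir.mkdir(exist_ok=True)
    for s, part in result.partitions.items():
        df = pd.DataFrame(
            {"gene_id": list(part.assignment), "module_index": list(part.assignment.values())}
        )
        df.to_csv(mods_dir / f"{s}.tsv", sep="\t", index=False)
        _sidecar(mods_dir / f"{s}.tsv", {"beta": part.beta, "r2": part.r2,
                                         "min_module_size": cfg.min_module_size,
                                         "cut_height": cfg.cut_height})
    edges_dir = out / "specific_edges"
    edges_dir.mkdir(exist_ok=True)
    for s, es in result.edge_sets.items():
        es.edges.to_csv(edges_dir / f"{s}.tsv", sep="\t", index=False)
        _sidecar(edges_dir / f"{s}.tsv", {"module": es.module, "E": cfg.E,
                                          "subtype": s,
                                          "module_genes": sorted(es.module_genes)})
    result.train_features.to_csv(out / "train_features.tsv", sep="\t")
    if not result.test_features.empty:
        result.test_features.to_csv(out / "test_features.tsv", sep="\t")
    result.model.to_json(out / "model.json")
    result.predictions.to_csv(out / "predictions.tsv", sep="\t")
    if result.report is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    **result.report.metrics(),
                    "classes": result.report.classes,
                    "confusion": result.report.confusion.tolist(),
                    "per_class_recall": result.report.per_class_recall.tolist(),
                },
                fh, indent=1,
            )
    with open(out / "split.json", "w") as fh:
        json.dump({"train": result.train_ids, "test": result.test_ids,
                   "seed": stage_seed(cfg.seed, "split")}, fh, indent=1)


def synthetic_config(seed: int = 0, E: int = 50, **overrides) -> PipelineConfig:
    """Pipeline configuration suited to the synthetic generator's scale.

    Synthetic values are already on a log-like scale, so no second log
    transform and no raw-scale mean floor.
    """
    base = dict(
        log_transform=False, min_mean=0.0, keep_fraction=0.9,
        alpha=0.01, min_module_size=10, cut_height=0.95,
        E=E, n_sets=10, test_fraction=0.1, seed=seed,
    )
    base.update(overrides)
    return PipelineConfig(**base)
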