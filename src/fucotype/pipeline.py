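"""End-to-end orchestration: train -> select -> classify -> filter ->
consensus -> report.

The pipeline trains both model families over their hyperparameter grids on
a labelled training set, scores every candidate on a held-out test set
(accuracy, target-decoy AUC, Pscore FDR cutoff), selects the best model per
family by Euclidean length, and applies the two winners jointly to new
data, reporting consensus classes filtered at the requested FDR.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .features import ExtractionParams, FeatureVector, extract_feature_table, feature_matrix
from .glycan import antennarity_class, format_glycopeptide_id
from .models import (
    DEFAULT_MARGIN_SEEDS,
    MarginModelSpec,
    NetworkSpec,
    TrainedModel,
    classify,
    default_margin_grid,
    train_margin,
    train_network,
)
from .scoring import (
    ModelPerformance,
    PscoreRecord,
    consensus,
    evaluate,
    evaluate_model,
    fdr_cutoff,
    make_decoys,
    decoy_pscores,
    pscores,
)
from .spectra import CLASS_ORDER, GsmRecord, read_gsm_table, read_mgf

logger = logging.getLogger("fucotype")

BUNDLE_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serialisable to one JSON file."""

    tolerance: float = 0.02
    snr_min: float = 3.0
    normalization: str = "base_peak"
    network_nodes: list[int] = field(default_factory=lambda: [8, 16, 32, 64, 128])
    network_layers: list[int] = field(default_factory=lambda: [3, 4, 5])
    network_epochs: list[int] = field(
        default_factory=lambda: [10, 100, 500, 1000, 2000, 5000, 10000, 20000])
    network_replicates: int = 10
    learning_rate: float = 0.02
    dropout_keep: float = 0.75
    margin_costs: list[float] | None = None  # None -> staged default grid
    margin_seeds: list[int] = field(default_factory=lambda: list(DEFAULT_MARGIN_SEEDS))
    fdr_q: float = 0.01
    decoy_repeats: int = 5
    consensus_rule: str = "union"
    seed: int = 0
    train_sources: list[str] | None = None  # None -> rows with source 'train'
    test_sources: list[str] | None = None

    @property
    def extraction(self) -> ExtractionParams:
        return ExtractionParams(self.tolerance, self.snr_min, self.normalization)

    def network_grid(self) -> list[NetworkSpec]:
        return [
            NetworkSpec(n, l, e, self.learning_rate, self.dropout_keep,
                        seed=self.seed + rep)
            for n in self.network_nodes
            for l in self.network_layers
            for e in self.network_epochs
            for rep in range(self.network_replicates)
        ]

    def margin_grid(self) -> list[MarginModelSpec]:
        return default_margin_grid(self.margin_costs, self.margin_seeds)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class FamilyResult:
    """Grid-search outcome for one model family."""

    best_model: TrainedModel
    best_performance: ModelPerformance
    performance_table: pd.DataFrame


@dataclass
class TrainResult:
    network: FamilyResult
    margin: FamilyResult
    config: PipelineConfig


def _grid_search(
    family: str,
    specs: Sequence[NetworkSpec | MarginModelSpec],
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    y_test: Sequence[str],
    config: PipelineConfig,
) -> FamilyResult:
    rows = []
    models: list[TrainedModel] = []
    t0 = time.time()
    for i, spec in enumerate(specs):
        if family == "network":
            model = train_network(X_train, y_train, spec)
        else:
            model = train_margin(X_train, y_train, spec)
        perf = evaluate_model(model, X_test, y_test, q=config.fdr_q,
                              decoy_repeats=config.decoy_repeats,
                              decoy_seed=config.seed)
        models.append(model)
        rows.append({**asdict(spec), "accuracy": perf.accuracy, "auc": perf.auc,
                     "euclidean_length": perf.euclidean_length,
                     "pscore_cutoff": perf.pscore_cutoff,
                     "n_filtered": perf.n_filtered})
        if (i + 1) % 10 == 0 or i + 1 == len(specs):
            logger.info("%s grid: %d/%d candidates (%.1fs)",
                        family, i + 1, len(specs), time.time() - t0)
    table = pd.DataFrame(rows)
    perfs = [ModelPerformance(r["accuracy"], r["auc"], r["pscore_cutoff"],
                              r["n_filtered"]) for r in rows]
    lengths = [p.euclidean_length for p in perfs]
    best = int(np.argmax(lengths))
    logger.info("%s family best: %s (EL=%.5f)", family, specs[best], lengths[best])
    return FamilyResult(models[best], perfs[best], table)


def train_and_select(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    y_test: Sequence[str],
    config: PipelineConfig,
) -> TrainResult:
    """Grid-train both families and pick each family's best model by
    Euclidean length on the test set."""
    if len(X_train) == 0:
        raise ValueError("empty training set")
    net = _grid_search("network", config.network_grid(),
                       X_train, y_train, X_test, y_test, config)
    mar = _grid_search("margin", config.margin_grid(),
                       X_train, y_train, X_test, y_test, config)
    return TrainResult(network=net, margin=mar, config=config)


def _split_by_source(gsms: Sequence[GsmRecord],
                     config: PipelineConfig) -> tuple[list[int], list[int]]:
    train_tags = set(config.train_sources or ["train"])
    test_tags = set(config.test_sources or ["test"])
    train_idx = [i for i, g in enumerate(gsms) if g.source in train_tags]
    test_idx = [i for i, g in enumerate(gsms) if g.source in test_tags]
    if not train_idx:
        raise ValueError(f"no GSMs with training source tag(s) {sorted(train_tags)}")
    if not test_idx:
        raise ValueError(f"no GSMs with test source tag(s) {sorted(test_tags)}")
    return train_idx, test_idx


def run_train(config: PipelineConfig, mgf_paths: Sequence[str],
              gsm_path: str, out_dir: str) -> TrainResult:
    """File-level training entry point.

    Reads spectra + labelled GSM table, splits train/test by the table's
    source column, grid-trains both families, and writes the model bundle
    and per-candidate performance tables into ``out_dir``.
    """
    spectra = [s for p in mgf_paths for s in read_mgf(p)]
    gsms = read_gsm_table(gsm_path)
    unlabeled = [g.spectrum_title for g in gsms if g.manual_label is None]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} GSM(s) lack a manual label (e.g. {unlabeled[:3]}); "
            "training needs labels — use the classify command for unknown sets"
        )
    fvs = extract_feature_table(spectra, gsms, config.extraction)
    X = feature_matrix(fvs)
    y = [g.manual_label for g in gsms]
    tr, te = _split_by_source(gsms, config)
    result = train_and_select(X[tr], [y[i] for i in tr], X[te], [y[i] for i in te],
                              config)
    os.makedirs(out_dir, exist_ok=True)
    save_bundle(result, os.path.join(out_dir, "model_bundle.joblib"))
    header = _provenance_header(config)
    for fam in ("network", "margin"):
        table = getattr(result, fam).performance_table
        path = os.path.join(out_dir, f"{fam}_grid_performance.tsv")
        with open(path, "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)
    with open(os.path.join(out_dir, "performance.json"), "w") as fh:
        json.dump(performance_summary(result), fh, indent=2)
    return result


def performance_summary(result: TrainResult) -> dict:
    out = {}
    for fam in ("network", "margin"):
        p = getattr(result, fam).best_performance
        out[fam] = {
            "accuracy": p.accuracy,
            "auc": p.auc,
            "euclidean_length": p.euclidean_length,
            "pscore_cutoff": p.pscore_cutoff,
            "n_filtered": p.n_filtered,
            "spec": asdict(getattr(result, fam).best_model.spec),
        }
    return out


def save_bundle(result: TrainResult, path: str) -> None:
    joblib.dump(
        {
            "format_version": BUNDLE_FORMAT_VERSION,
            "fucotype_version": __version__,
            "network": result.network.best_model,
            "margin": result.margin.best_model,
            "config": asdict(result.config),
        },
        path,
    )


def load_bundle(path: str) -> dict:
    bundle = joblib.load(path)
    if bundle.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model bundle format {bundle.get('format_version')!r}")
    return bundle


@dataclass
class ClassifyResult:
    table: pd.DataFrame
    network_cutoff: float
    margin_cutoff: float
    metrics: dict | None = None


def classify_set(
    network_model: TrainedModel,
    margin_model: TrainedModel,
    fvs: Sequence[FeatureVector],
    config: PipelineConfig,
) -> ClassifyResult:
    """Classify one GSM set with both models, filter each at the decoy FDR
    computed on this same set, and derive consensus classes."""
    if not fvs:
        return ClassifyResult(pd.DataFrame(
            columns=["title", "glycopeptide_id", "antennarity", "dnn_class",
                     "dnn_pscore", "dnn_passed_fdr", "svm_class", "svm_pscore",
                     "svm_passed_fdr", "consensus_class", "manual_label"]),
            math.inf, math.inf)
    X = feature_matrix(fvs)
    gsms = [fv.gsm for fv in fvs]
    records = {}
    cutoffs = {}
    for name, model in (("network", network_model), ("margin", margin_model)):
        proba = model.predict_proba(X)
        target = pscores(proba)
        decoys = make_decoys(X, n_repeats=config.decoy_repeats, seed=config.seed)
        decoy = decoy_pscores(model, decoys)
        cutoff, _ = fdr_cutoff(target, decoy, q=config.fdr_q)
        cutoffs[name] = cutoff
        records[name] = [
            PscoreRecord(gsm=g.spectrum_title, predicted_class=classify(p),
                         pscore=float(s))
            for g, p, s in zip(gsms, proba, target)
        ]
    cons = dict(consensus(records["network"], records["margin"],
                          cutoffs["network"], cutoffs["margin"],
                          rule=config.consensus_rule))
    rows = []
    for g, net_rec, mar_rec in zip(gsms, records["network"], records["margin"]):
        rows.append({
            "title": g.spectrum_title,
            "glycopeptide_id": format_glycopeptide_id(g.glycopeptide),
            "antennarity": antennarity_class(g.glycopeptide.composition),
            "dnn_class": net_rec.predicted_class,
            "dnn_pscore": round(net_rec.pscore, 6),
            "dnn_passed_fdr": net_rec.pscore >= cutoffs["network"],
            "svm_class": mar_rec.predicted_class,
            "svm_pscore": round(mar_rec.pscore, 6),
            "svm_passed_fdr": mar_rec.pscore >= cutoffs["margin"],
            "consensus_class": cons.get(g.spectrum_title, ""),
            "manual_label": g.manual_label or "",
        })
    table = pd.DataFrame(rows)
    metrics = None
    labels = [g.manual_label for g in gsms]
    if all(l is not None for l in labels) and labels:
        predicted = [cons.get(g.spectrum_title) for g in gsms]
        accuracy, sensitivity, confusion = evaluate(predicted, labels)
        metrics = summarize_metrics(accuracy, sensitivity, confusion, table)
    return ClassifyResult(table=table, network_cutoff=cutoffs["network"],
                          margin_cutoff=cutoffs["margin"], metrics=metrics)


def summarize_metrics(accuracy: float, sensitivity: float,
                      confusion: np.ndarray, table: pd.DataFrame) -> dict:
    per_class = {
        c: int((table["consensus_class"] == c).sum()) for c in CLASS_ORDER
    }
    per_antennarity = (
        table[table["consensus_class"] != ""]
        .groupby(["antennarity", "consensus_class"]).size()
    )
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "n_consensus": int((table["consensus_class"] != "").sum()),
        "n_total": len(table),
        "confusion": {
            m: {p: int(confusion[i, j]) for j, p in enumerate(CLASS_ORDER)}
            for i, m in enumerate(CLASS_ORDER)
        },
        "consensus_counts_per_class": per_class,
        "consensus_counts_per_antennarity": {
            f"{a}/{c}": int(n) for (a, c), n in per_antennarity.items()
        },
    }


def run_classify(config: PipelineConfig, bundle_path: str,
                 mgf_paths: Sequence[str], gsm_path: str,
                 out_dir: str) -> ClassifyResult:
    """File-level classification entry point for unknown (or labelled) sets."""
    bundle = load_bundle(bundle_path)
    spectra = [s for p in mgf_paths for s in read_mgf(p)]
    gsms = read_gsm_table(gsm_path)
    fvs = extract_feature_table(spectra, gsms, config.extraction)
    result = classify_set(bundle["network"], bundle["margin"], fvs, config)
    os.makedirs(out_dir, exist_ok=True)
    out_path = os.path.join(out_dir, "classification.tsv")
    with open(out_path, "w") as fh:
        fh.write(_provenance_header(config))
        fh.write(f"# network_pscore_cutoff: {result.network_cutoff}\n")
        fh.write(f"# margin_pscore_cutoff: {result.margin_cutoff}\n")
        result.table.to_csv(fh, sep="\t", index=False)
    if result.metrics is not None:
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(result.metrics, fh, indent=2)
    return result


def run_evaluate(results_path: str, labels_path: str) -> dict:
    """Compare a classification table against a labelled GSM table."""
    table = pd.read_csv(results_path, sep="\t", comment="#",
                        keep_default_na=False)
    gsms = read_gsm_table(labels_path)
    manual = {g.spectrum_title: g.manual_label for g in gsms
              if g.manual_label is not None}
    shared = [t for t in table["title"] if t in manual]
    if not shared:
        raise ValueError("no overlapping titles between results and label table")
    sub = table[table["title"].isin(manual)]
    predicted = [c if c else None for c in sub["consensus_class"]]
    labels = [manual[t] for t in sub["title"]]
    accuracy, sensitivity, confusion = evaluate(predicted, labels)
    return summarize_metrics(accuracy, sensitivity, confusion, sub)


def _provenance_header(config: PipelineConfig) -> str:
    return (f"# fucotype {__version__}\n"
            f"# config_sha256: {config.digest()}\n"
            f"# seed: {config.seed}\n")
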