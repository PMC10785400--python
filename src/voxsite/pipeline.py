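"""End-to-end orchestration: corpus → features → model → site predictions.

Thin glue over the library modules so the CLI, the examples and the tests
all drive the identical code path. A single global seed fans out
deterministically to per-stage seeds (simulate / select / train) via a seed
sequence, so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from voxsite import adapters, selector, scorer, sitepredict, voxelizer
from voxsite.evaluate import site_distance, summarize
from voxsite.structmodel import MoleculeStructure, load_structure
from voxsite.synthetic import ScenarioConfig, generate_corpus

log = logging.getLogger(__name__)


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single global seed out to named per-stage seeds (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    names = ["simulate_train", "simulate_eval", "select", "train"]
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


@dataclass
class CorpusTarget:
    """One loaded corpus entry: structures, report and (optionally) truth."""

    target_id: str
    protein: MoleculeStructure
    report: adapters.ProgramReport
    crystal_ligand: MoleculeStructure | None = None
    true_site: np.ndarray | None = None


def load_corpus(corpus_dir) -> list[CorpusTarget]:
    """Read a corpus directory written by ``synthetic.generate_corpus`` (or
    assembled by hand in the same layout) via the manifest CSV."""
    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    targets = []
    for _, row in manifest.iterrows():
        ligand = None
        if isinstance(row.get("ligand"), str):
            ligand = load_structure(corpus_dir / row["ligand"], kind="ligand")
        true_site = None
        if {"true_x", "true_y", "true_z"} <= set(manifest.columns):
            true_site = np.array([row["true_x"], row["true_y"], row["true_z"]])
        targets.append(CorpusTarget(
            target_id=str(row["target_id"]),
            protein=load_structure(corpus_dir / row["protein"], kind="protein"),
            report=adapters.read_interchange(corpus_dir / row["interchange"]),
            crystal_ligand=ligand,
            true_site=true_site,
        ))
    return targets


def featurize_corpus(targets: list[CorpusTarget], resolution: float = 10.0,
                     padding: float = 5.0, labeled: bool = True
                     ) -> list[voxelizer.FeatureTable]:
    """Grid, featurize, drop empty voxels and (when ligands are present)
    label each target."""
    tables = []
    for t in targets:
        grid = voxelizer.build_grid(t.protein, resolution, padding)
        table = voxelizer.featurize_target(grid, t.report)
        table = voxelizer.filter_empty(table)
        if labeled and t.crystal_ligand is not None:
            table = voxelizer.label_rows(table, t.crystal_ligand)
        tables.append(table)
    return tables


@dataclass
class TrainedBundle:
    model: scorer.SiteScorer
    decisions: list[selector.FeatureDecision]
    column_means: dict[str, float]
    feature_names: list[str]


def train_pipeline(tables: list[voxelizer.FeatureTable],
                   boruta_config: selector.BorutaConfig | None = None,
                   stack_config: scorer.StackConfig | None = None,
                   keep_tentative: bool = False) -> TrainedBundle:
    """Align → impute → shadow-feature selection → stacked-scorer training."""
    tables = voxelizer.align_tables(tables)
    means = voxelizer.fit_impute(tables)
    tables = [voxelizer.apply_impute(t, means) for t in tables]
    X = np.vstack([t.X for t in tables])
    y = np.concatenate([(t.y == voxelizer.POSITIVE).astype(int) for t in tables])
    decisions = selector.boruta_select(X, y, boruta_config,
                                       feature_names=tables[0].feature_names)
    selected = [selector.apply_selection(t, decisions, keep_tentative)
                for t in tables]
    model = scorer.train(selected, stack_config)
    return TrainedBundle(model, decisions, means, list(tables[0].feature_names))


def prepare_for_scoring(table: voxelizer.FeatureTable,
                        bundle: TrainedBundle) -> voxelizer.FeatureTable:
    """Project an unseen target's table onto the model's feature space:
    add never-seen columns as missing, impute with training means, and keep
    the selected columns in training order."""
    work = table.copy()
    for c in bundle.feature_names:
        if c not in work.frame:
            work.frame[c] = np.nan
    work.frame = work.frame[
        voxelizer.INDEX_COLS + voxelizer.CENTER_COLS + bundle.feature_names
        + [voxelizer.LABEL_COL]
    ]
    work.feature_names = list(bundle.feature_names)
    work = voxelizer.apply_impute(work, bundle.column_means)
    keep = bundle.model.selected_features
    work.frame = work.frame[
        voxelizer.INDEX_COLS + voxelizer.CENTER_COLS + keep + [voxelizer.LABEL_COL]
    ]
    work.feature_names = list(keep)
    work.column_means = {c: bundle.column_means[c] for c in keep}
    return work


def predict_sites(bundle: TrainedBundle, target: CorpusTarget,
                  table: voxelizer.FeatureTable | None = None, k: int = 1,
                  resolution: float = 10.0, padding: float = 5.0
                  ) -> list[sitepredict.SitePrediction]:
    """Score voxels of one target and map the ranking to cavities."""
    if table is None:
        grid = voxelizer.build_grid(target.protein, resolution, padding)
        table = voxelizer.filter_empty(voxelizer.featurize_target(grid, target.report))
    work = prepare_for_scoring(table, bundle)
    scores = scorer.score_voxels(bundle.model, work)
    ranked = sitepredict.rank_voxels(scores, work)
    return sitepredict.top_k_sites(ranked, scores, work.grid,
                                   target.report.cavities, k=k)


def evaluate_sites(bundle: TrainedBundle, targets: list[CorpusTarget],
                   dataset: str = "synthetic") -> pd.DataFrame:
    """Site-prediction metrics for every target with a crystal ligand."""
    rows = []
    for t in targets:
        if t.crystal_ligand is None:
            continue
        pred = predict_sites(bundle, t, k=1)[0]
        res = site_distance(pred, t.crystal_ligand, target_id=t.target_id)
        rows.append({
            "target_id": t.target_id,
            "dataset": dataset,
            "predicted_x": res.predicted_centroid[0],
            "predicted_y": res.predicted_centroid[1],
            "predicted_z": res.predicted_centroid[2],
            "distance": res.distance,
            "hit_8A": res.hit_8A,
            "provenance": pred.provenance,
        })
    return pd.DataFrame(rows)


def run_e2e(run_dir, seed: int = 0, n_train: int = 60, n_eval: int = 20,
            scenario: ScenarioConfig | None = None,
            boruta_config: selector.BorutaConfig | None = None,
            stack_config: scorer.StackConfig | None = None,
            overwrite: bool = False) -> dict:
    """Simulate → featurize → train → predict → evaluate, writing every stage
    product under ``run_dir``. Returns the summary metrics dict."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)

    base = scenario or ScenarioConfig()
    train_cfg = ScenarioConfig(**{**base.__dict__, "n_targets": n_train,
                                  "seed": seeds["simulate_train"]})
    eval_cfg = ScenarioConfig(**{**base.__dict__, "n_targets": n_eval,
                                 "seed": seeds["simulate_eval"]})
    train_dir = generate_corpus(train_cfg, run_dir / "corpus_train", overwrite)
    eval_dir = generate_corpus(eval_cfg, run_dir / "corpus_eval", overwrite)

    train_targets = load_corpus(train_dir)
    eval_targets = load_corpus(eval_dir)
    train_tables = featurize_corpus(train_targets)

    boruta_config = boruta_config or selector.BorutaConfig(seed=seeds["select"])
    stack_config = stack_config or scorer.StackConfig(seed=seeds["train"])
    bundle = train_pipeline(train_tables, boruta_config, stack_config)

    selector.decisions_to_frame(bundle.decisions).to_csv(
        run_dir / "feature_decisions.csv", index=False)
    bundle.model.save(run_dir / "model")

    results = evaluate_sites(bundle, eval_targets)
    results.to_csv(run_dir / "site_metrics.csv", index=False)

    summary = {
        "n_eval_targets": int(len(results)),
        "site_accuracy_8A": float(results["hit_8A"].mean()),
        "mean_distance_A": float(results["distance"].mean()),
        "median_distance_A": float(results["distance"].median()),
        "validation_auroc": bundle.model.training_report.get("auroc"),
    }
    pd.DataFrame([summary]).to_csv(run_dir / "summary.csv", index=False)
    return summary
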