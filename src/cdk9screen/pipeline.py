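"""End-to-end orchestration: synthesize/curate, featurize, train the
model zoo, rank by test MCC, and screen a library.

This module wires the stage modules together for the common campaign
shapes; each stage remains usable on its own.  The zoo trains every
(algorithm x representation) combination — 35 models per labeling
scheme with the full grids — selects hyperparameters by grid-search CV
on the training split only, refits on the full training set, and
evaluates once on the held-out test split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cdk9screen import datasets, evaluate, features, models, screen, synthdata


def featurize_splits(
    train_smiles: list[str],
    test_smiles: list[str],
    kinds=features.ALL_KINDS,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], features.ScalerModel]:
    """Feature matrices for both splits, computing each block once.

    The descriptor scaler is fitted on the training split only; hybrids
    are assembled from the cached fingerprint and descriptor blocks.
    """
    kinds = list(kinds)
    fp_needed = {features.HYBRID_PARTS.get(k, k) for k in kinds} & set(features.FP_KINDS)
    fp_cache = {
        k: (
            features.featurize_matrix(train_smiles, k),
            features.featurize_matrix(test_smiles, k),
        )
        for k in fp_needed
    }
    scaler = features.fit_descriptor_scaler(train_smiles)
    needs_desc = any(k == "descriptors" or k in features.HYBRID_PARTS for k in kinds)
    if needs_desc:
        raw_tr = np.vstack([features.descriptors(s).values for s in train_smiles])
        raw_te = (
            np.vstack([features.descriptors(s).values for s in test_smiles])
            if test_smiles
            else np.zeros((0, features.KIND_LENGTHS["descriptors"]))
        )
        desc_tr = features.apply_minmax(scaler, raw_tr)
        desc_te = features.apply_minmax(scaler, raw_te)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k in kinds:
        if k in fp_cache:
            out[k] = fp_cache[k]
        elif k == "descriptors":
            out[k] = (desc_tr, desc_te)
        else:
            base = features.HYBRID_PARTS[k]
            out[k] = (
                np.hstack([fp_cache[base][0], desc_tr]),
                np.hstack([fp_cache[base][1], desc_te]),
            )
    return out, scaler


@dataclass
class ZooEntry:
    record: dict
    model: models.TrainedModel
    tuning: models.GridSearchResult
    cv: models.CVResult


def train_zoo(
    pair: datasets.DatasetPair,
    seed: int,
    algorithms=models.ALGORITHMS,
    representations=features.ALL_KINDS,
    grids: dict[str, list[dict]] | None = None,
) -> tuple[list[ZooEntry], features.ScalerModel]:
    """Tune, cross-validate, refit and test every zoo combination."""
    grids = grids or models.GRIDS
    y_train = (pair.train["label"] == "active").to_numpy().astype(int)
    y_test = (pair.test["label"] == "active").to_numpy().astype(int)
    mats, scaler = featurize_splits(
        pair.train["parent_smiles"].tolist(),
        pair.test["parent_smiles"].tolist(),
        kinds=representations,
    )
    entries = []
    for kind in representations:
        X_train, X_test = mats[kind]
        for algorithm in algorithms:
            tuning = models.grid_search(
                algorithm, X_train, y_train, seed=seed, grid=grids[algorithm]
            )
            cv = models.five_fold_cv(
                algorithm, tuning.best_params, X_train, y_train, seed=seed
            )
            spec = models.ModelSpec(algorithm, kind, tuning.best_params, seed)
            model = models.fit_final(spec, X_train, y_train)
            ps = models.predict_ps(model, X_test)
            rep = evaluate.metrics_report(ps, y_test)
            entries.append(
                ZooEntry(
                    record={
                        "algorithm": algorithm,
                        "representation": kind,
                        "scheme": pair.scheme.name,
                        "hyperparams": tuning.best_params,
                        "cv_mean_mcc": cv.mean,
                        "cv_sd_mcc": cv.sd,
                        "mcc": rep.mcc,
                        "precision": rep.precision,
                        "recall": rep.recall,
                    },
                    model=model,
                    tuning=tuning,
                    cv=cv,
                )
            )
    return entries, scaler


@dataclass
class CampaignConfig:
    """Shape of a full synthetic screening campaign."""

    n_compounds: int = 1000
    n_decoys: int = 1500
    library_size: int = 10_000
    seed: int = 0
    grids: dict[str, list[dict]] = field(default_factory=lambda: models.REDUCED_GRIDS)
    algorithms: tuple = models.ALGORITHMS
    representations: tuple = features.ALL_KINDS
    ps_min: float = screen.DEFAULT_PS_MIN
    cut: float = screen.DEFAULT_CUT


@dataclass
class CampaignResult:
    pairs: list
    funnel: datasets.FunnelReport
    ranking: pd.DataFrame
    best: ZooEntry
    curve: evaluate.ThresholdCurve
    scored: pd.DataFrame
    hits: pd.DataFrame
    assignment: screen.ClusterAssignment
    representatives: pd.DataFrame
    skipped_clusters: list[str]
    elapsed_s: float


def run_campaign(cfg: CampaignConfig) -> CampaignResult:
    """Synthetic data -> curation -> zoo -> ranking -> screening -> hits."""
    t0 = time.time()
    synth_cfg = synthdata.SynthConfig(n_compounds=cfg.n_compounds, seed=cfg.seed)
    library = synthdata.generate_library(synth_cfg)
    table = synthdata.assign_activities(library, synth_cfg)
    decoys = synthdata.generate_decoys(cfg.n_decoys, seed=cfg.seed + 101)
    pairs, funnel = datasets.build_datasets(table, decoys, seed=cfg.seed)

    all_entries: list[ZooEntry] = []
    scalers: dict[str, features.ScalerModel] = {}
    for pair in pairs:
        entries, scaler = train_zoo(
            pair,
            seed=cfg.seed,
            algorithms=cfg.algorithms,
            representations=cfg.representations,
            grids=cfg.grids,
        )
        scalers[pair.scheme.name] = scaler
        all_entries.extend(entries)

    ranking = evaluate.rank_models([e.record for e in all_entries])
    best_key = (
        ranking.iloc[0]["algorithm"],
        ranking.iloc[0]["representation"],
        ranking.iloc[0]["scheme"],
    )
    best = next(
        e
        for e in all_entries
        if (
            e.record["algorithm"],
            e.record["representation"],
            e.record["scheme"],
        )
        == best_key
    )
    best_pair = next(p for p in pairs if p.scheme.name == best.record["scheme"])
    y_test = (best_pair.test["label"] == "active").to_numpy().astype(int)
    mats, _ = featurize_splits(
        best_pair.train["parent_smiles"].tolist(),
        best_pair.test["parent_smiles"].tolist(),
        kinds=[best.record["representation"]],
    )
    ps_test = models.predict_ps(best.model, mats[best.record["representation"]][1])
    curve = evaluate.sweep_thresholds(ps_test, y_test)

    raw_library = synthdata.generate_screening_library(
        cfg.library_size, seed=cfg.seed + 202
    )
    std_library, _rejects = screen.standardize_library(raw_library)
    scored = screen.score_library(
        best.model, std_library, scaler=scalers[best.record["scheme"]]
    )
    hits = screen.filter_hits(scored, ps_min=cfg.ps_min)
    assignment = screen.cluster_hits(hits, cut=cfg.cut)
    representatives, skipped = screen.select_representatives(assignment, hits)
    return CampaignResult(
        pairs=pairs,
        funnel=funnel,
        ranking=ranking,
        best=best,
        curve=curve,
        scored=scored,
        hits=hits,
        assignment=assignment,
        representatives=representatives,
        skipped_clusters=skipped,
        elapsed_s=time.time() - t0,
    )
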