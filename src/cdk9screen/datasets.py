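"""Bioactivity curation funnel: from raw activity records to balanced,
labeled train/test datasets.

The funnel mirrors standard practice for assembling classification data
from public bioactivity repositories:

1. record filtering — keep exact ("=") measurements of IC50/EC50/Ki/Kd
   with a parseable structure and a known unit; censored (">") records
   go to a side pool, everything else is rejected with a reason code;
2. train/test partition by activity type — IC50 records (the dominant
   type) train the models, EC50/Ki/Kd records form the independent test
   set; a compound measured both ways keeps only its IC50 record;
3. deduplication — one record per standardized structure, multiple
   exact values collapsing to the median pActivity; structures present
   in both pools stay in training only;
4. threshold labeling under a scheme — Lead-Oriented (active pActivity
   >= 6, inactive <= 5.30) or Potency-Oriented (active >= 7.5,
   inactive <= 5.5); the exclusion window between the thresholds is
   dropped to avoid boundary ambiguity;
5. censored augmentation — "> value" records certify inactivity when
   the bound meets the scheme's inactivity concentration cutoff (5 uM
   for LO, 3.2 uM for PO);
6. decoy balancing — presumed-inactive drug-like decoys are sampled
   without replacement until both classes are equal in each split.

pActivity is -log10 of the molar activity value (1 uM <-> 6.0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from cdk9screen.standardize import RawCompound, StandardizationError, strip_to_parent

ACTIVITY_TYPES = ("IC50", "EC50", "Ki", "Kd")
UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}

REASON_BAD_RELATION = "unknown_relation"
REASON_BAD_TYPE = "unknown_activity_type"
REASON_BAD_UNIT = "unknown_unit"
REASON_BAD_VALUE = "missing_or_nonpositive_value"


@dataclass(frozen=True)
class SchemeParams:
    """A classification scheme: pActivity thresholds and the censoring cutoff.

    ``active_min_p``/``inactive_max_p`` bound the active and inactive
    classes (both inclusive); the window between them is excluded.
    ``inactive_min_conc_um`` is the concentration a censored "> value"
    record must reach to certify inactivity.
    """

    name: str
    active_min_p: float
    inactive_max_p: float
    inactive_min_conc_um: float

    def __post_init__(self):
        if self.active_min_p <= self.inactive_max_p:
            raise ValueError("exclusion window is empty")


LEAD_ORIENTED = SchemeParams("LO", active_min_p=6.0, inactive_max_p=5.30,
                             inactive_min_conc_um=5.0)
POTENCY_ORIENTED = SchemeParams("PO", active_min_p=7.5, inactive_max_p=5.5,
                                inactive_min_conc_um=3.2)
DEFAULT_SCHEMES = (LEAD_ORIENTED, POTENCY_ORIENTED)


@dataclass
class DatasetPair:
    """Balanced, disjoint train/test splits under one scheme.

    Both frames carry columns std_key, parent_smiles, label
    (active|inactive), source (measured|censored_gt|decoy).
    """

    scheme: SchemeParams
    train: pd.DataFrame
    test: pd.DataFrame


@dataclass
class FunnelReport:
    """Per-stage record accounting; every input lands in exactly one bin."""

    counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts, fh, indent=2)


# ---------------------------------------------------------------------------
# Stage 1: filtering and standardization
# ---------------------------------------------------------------------------

def curate_records(
    table: pd.DataFrame,
    smiles_col: str = "smiles",
    id_col: str = "compound_id",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Filter, standardize and annotate raw activity records.

    Returns ``(exact, censored, rejects)``.  Exact and censored frames
    carry std_key, parent_smiles, activity_type, pActivity (exact only)
    and value_molar; rejects carry a reason code.  Standardization is
    cached per unique SMILES string, so salt forms repeated across rows
    cost one call.
    """
    exact_rows, censored_rows, reject_rows = [], [], []
    std_cache: dict[str, tuple[str, str] | StandardizationError] = {}
    for row in table.itertuples(index=False):
        cid = str(getattr(row, id_col))
        smiles = getattr(row, smiles_col)
        relation = getattr(row, "relation")
        a_type = getattr(row, "activity_type")
        value = getattr(row, "value")
        units = getattr(row, "units")

        if relation not in ("=", ">"):
            reject_rows.append((cid, REASON_BAD_RELATION))
            continue
        if a_type not in ACTIVITY_TYPES:
            reject_rows.append((cid, REASON_BAD_TYPE))
            continue
        if units not in UNIT_TO_MOLAR:
            reject_rows.append((cid, REASON_BAD_UNIT))
            continue
        try:
            value = float(value)
        except (TypeError, ValueError):
            value = float("nan")
        if not math.isfinite(value) or value <= 0:
            reject_rows.append((cid, REASON_BAD_VALUE))
            continue

        smiles_str = "" if smiles is None or (isinstance(smiles, float) and math.isnan(smiles)) else str(smiles)
        cached = std_cache.get(smiles_str)
        if cached is None:
            try:
                std = strip_to_parent(RawCompound(cid, smiles_str))
                cached = (std.std_key, std.parent_smiles)
            except StandardizationError as err:
                cached = err
            std_cache[smiles_str] = cached
        if isinstance(cached, StandardizationError):
            reject_rows.append((cid, cached.reason))
            continue
        std_key, parent_smiles = cached

        value_molar = value * UNIT_TO_MOLAR[units]
        rec = {
            "compound_id": cid,
            "std_key": std_key,
            "parent_smiles": parent_smiles,
            "activity_type": a_type,
            "value_molar": value_molar,
        }
        if relation == "=":
            rec["pActivity"] = -math.log10(value_molar)
            exact_rows.append(rec)
        else:
            censored_rows.append(rec)

    exact = pd.DataFrame(
        exact_rows,
        columns=["compound_id", "std_key", "parent_smiles", "activity_type",
                 "value_molar", "pActivity"],
    )
    censored = pd.DataFrame(
        censored_rows,
        columns=["compound_id", "std_key", "parent_smiles", "activity_type",
                 "value_molar"],
    )
    rejects = pd.DataFrame(reject_rows, columns=["compound_id", "reason"])
    return exact, censored, rejects


# ---------------------------------------------------------------------------
# Stages 2-3: partition by activity type, deduplicate
# ---------------------------------------------------------------------------

def partition_by_type(exact: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IC50 records -> training pool; EC50/Ki/Kd -> test pool.

    A compound measured with IC50 and another type keeps only the IC50
    record (training enrichment); its non-IC50 rows are dropped.
    """
    is_ic50 = exact["activity_type"] == "IC50"
    train_pool = exact[is_ic50].copy()
    ic50_keys = set(train_pool["std_key"])
    test_pool = exact[~is_ic50 & ~exact["std_key"].isin(ic50_keys)].copy()
    return train_pool, test_pool


def deduplicate(pool: pd.DataFrame) -> pd.DataFrame:
    """One record per std_key; exact values collapse to the median pActivity."""
    if pool.empty:
        return pool.copy()
    agg = (
        pool.groupby("std_key", sort=True)
        .agg(
            compound_id=("compound_id", "first"),
            parent_smiles=("parent_smiles", "first"),
            pActivity=("pActivity", "median"),
        )
        .reset_index()
    )
    return agg


def drop_train_overlap(
    train_pool: pd.DataFrame, test_pool: pd.DataFrame
) -> pd.DataFrame:
    """Remove test records whose structure also trains (train priority)."""
    return test_pool[~test_pool["std_key"].isin(set(train_pool["std_key"]))].copy()


# ---------------------------------------------------------------------------
# Stage 4: threshold labeling
# ---------------------------------------------------------------------------

def assign_labels(pool: pd.DataFrame, scheme: SchemeParams) -> pd.DataFrame:
    """Label by pActivity; the exclusion window between thresholds drops out."""
    out = pool.copy()
    active = out["pActivity"] >= scheme.active_min_p
    inactive = out["pActivity"] <= scheme.inactive_max_p
    out["label"] = np.where(active, "active", np.where(inactive, "inactive", ""))
    out = out[out["label"] != ""].copy()
    out["source"] = "measured"
    return out[["std_key", "parent_smiles", "label", "source", "pActivity"]]


def count_window_excluded(pool: pd.DataFrame, scheme: SchemeParams) -> int:
    p = pool["pActivity"]
    return int(((p > scheme.inactive_max_p) & (p < scheme.active_min_p)).sum())


# ---------------------------------------------------------------------------
# Stage 5: censored augmentation
# ---------------------------------------------------------------------------

def augment_censored_inactives(
    censored_pool: pd.DataFrame, scheme: SchemeParams
) -> pd.DataFrame:
    """"> value" records certify inactivity when value >= the scheme cutoff."""
    if censored_pool.empty:
        return pd.DataFrame(
            columns=["std_key", "parent_smiles", "label", "source", "pActivity"]
        )
    cutoff_molar = scheme.inactive_min_conc_um * 1e-6
    ok = censored_pool["value_molar"] >= cutoff_molar * (1 - 1e-12)
    kept = censored_pool[ok].drop_duplicates("std_key").copy()
    kept["label"] = "inactive"
    kept["source"] = "censored_gt"
    kept["pActivity"] = np.nan
    return kept[["std_key", "parent_smiles", "label", "source", "pActivity"]]


# ---------------------------------------------------------------------------
# Stage 6: decoy balancing
# ---------------------------------------------------------------------------

def balance_with_decoys(
    dataset: pd.DataFrame, decoy_pool: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add decoys (label inactive) until classes are equal.

    ``decoy_pool`` needs columns std_key and parent_smiles.  Sampling is
    uniform without replacement with a fixed seed.  Returns the balanced
    dataset and the remaining (unused) decoy pool, so successive calls
    for train and test never reuse a decoy.  Raises if the pool is too
    small or if inactives already outnumber actives.
    """
    n_active = int((dataset["label"] == "active").sum())
    n_inactive = int((dataset["label"] == "inactive").sum())
    if n_inactive > n_active:
        raise ValueError(
            f"inactive class ({n_inactive}) exceeds active ({n_active}); "
            "decoy balancing only adds inactives"
        )
    need = n_active - n_inactive
    if need > len(decoy_pool):
        raise ValueError(
            f"decoy pool too small: need {need}, have {len(decoy_pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(decoy_pool), size=need, replace=False)
    chosen = decoy_pool.iloc[np.sort(idx)].copy()
    remaining = decoy_pool.drop(decoy_pool.index[np.sort(idx)])
    chosen["label"] = "inactive"
    chosen["source"] = "decoy"
    chosen["pActivity"] = np.nan
    chosen = chosen[["std_key", "parent_smiles", "label", "source", "pActivity"]]
    if chosen.empty:
        return dataset.reset_index(drop=True), remaining
    out = pd.concat([dataset, chosen], ignore_index=True)
    return out, remaining


# ---------------------------------------------------------------------------
# Whole funnel
# ---------------------------------------------------------------------------

def build_datasets(
    activity_table: pd.DataFrame,
    decoy_smiles: Iterable[str],
    schemes: Iterable[SchemeParams] = DEFAULT_SCHEMES,
    seed: int = 0,
) -> tuple[list[DatasetPair], FunnelReport]:
    """Run the complete curation funnel and emit one DatasetPair per scheme.

    Decoys are standardized with the same protocol, deduplicated against
    the measured compounds, and consumed without replacement across the
    train and test splits of each scheme.  Raises when a class would be
    empty after labeling (naming the stage), or when the decoy pool runs
    short.
    """
    report = FunnelReport()
    exact, censored, rejects = curate_records(activity_table)
    report.counts["input_records"] = int(len(activity_table))
    report.counts["rejected"] = int(len(rejects))
    report.counts["exact_records"] = int(len(exact))
    report.counts["censored_records"] = int(len(censored))
    report.counts["reject_reasons"] = (
        rejects["reason"].value_counts().to_dict() if len(rejects) else {}
    )

    train_pool, test_pool = partition_by_type(exact)
    report.counts["train_pool_records"] = int(len(train_pool))
    report.counts["test_pool_records"] = int(len(test_pool))
    report.counts["dropped_nonic50_of_trained_compounds"] = int(
        len(exact) - len(train_pool) - len(test_pool)
    )

    train_pool = deduplicate(train_pool)
    test_pool = deduplicate(test_pool)
    test_pool = drop_train_overlap(train_pool, test_pool)
    report.counts["train_pool_unique"] = int(len(train_pool))
    report.counts["test_pool_unique"] = int(len(test_pool))

    cens_train = censored[censored["activity_type"] == "IC50"]
    cens_test = censored[censored["activity_type"] != "IC50"]

    # standardize + deduplicate the decoy library once
    measured_keys = set(exact["std_key"]) | set(censored["std_key"])
    decoy_rows, seen = [], set()
    for i, smi in enumerate(decoy_smiles):
        std = strip_to_parent(RawCompound(f"DECOY{i:06d}", smi))
        if std.std_key in seen or std.std_key in measured_keys:
            continue
        seen.add(std.std_key)
        decoy_rows.append((std.std_key, std.parent_smiles))
    decoy_pool_full = pd.DataFrame(decoy_rows, columns=["std_key", "parent_smiles"])
    report.counts["decoy_pool"] = int(len(decoy_pool_full))

    pairs = []
    for scheme_i, scheme in enumerate(schemes):
        sc: dict = {}
        train_labeled = assign_labels(train_pool, scheme)
        test_labeled = assign_labels(test_pool, scheme)
        sc["train_window_excluded"] = count_window_excluded(train_pool, scheme)
        sc["test_window_excluded"] = count_window_excluded(test_pool, scheme)

        cens_train_aug = augment_censored_inactives(cens_train, scheme)
        cens_test_aug = augment_censored_inactives(cens_test, scheme)
        # keep the splits disjoint: a censored structure never enters both
        cens_train_aug = cens_train_aug[
            ~cens_train_aug["std_key"].isin(set(test_labeled["std_key"]))
        ]
        cens_test_aug = cens_test_aug[
            ~cens_test_aug["std_key"].isin(set(train_labeled["std_key"]))
            & ~cens_test_aug["std_key"].isin(set(cens_train_aug["std_key"]))
        ]
        def _concat(a, b):
            frames = [f for f in (a, b) if not f.empty]
            if not frames:
                return a
            return pd.concat(frames, ignore_index=True)

        train = _concat(train_labeled, cens_train_aug).drop_duplicates("std_key")
        test = _concat(test_labeled, cens_test_aug).drop_duplicates("std_key")
        sc["train_censored_added"] = int(len(cens_train_aug))
        sc["test_censored_added"] = int(len(cens_test_aug))

        for split_name, frame in (("train", train), ("test", test)):
            for cls in ("active", "inactive"):
                if not (frame["label"] == cls).any():
                    raise ValueError(
                        f"{scheme.name} {split_name}: empty {cls} class "
                        "after labeling/augmentation"
                    )

        # Balancing adds inactives only; if a split ends up with an
        # inactive majority (possible by sampling noise near the class
        # boundary), uniformly down-sample the inactives to the active
        # count so that every emitted dataset is perfectly balanced.
        def _cap_inactives(frame: pd.DataFrame, which: str, cap_seed: int):
            n_active = int((frame["label"] == "active").sum())
            inactive_idx = frame.index[frame["label"] == "inactive"]
            excess = len(inactive_idx) - n_active
            if excess <= 0:
                return frame
            rng = np.random.default_rng(cap_seed)
            drop = rng.choice(inactive_idx, size=excess, replace=False)
            sc[f"{which}_inactive_downsampled"] = int(excess)
            return frame.drop(index=drop)

        train = _cap_inactives(train, "train", seed * 1000 + scheme_i * 4 + 2)
        test = _cap_inactives(test, "test", seed * 1000 + scheme_i * 4 + 3)

        decoy_pool = decoy_pool_full
        train, decoy_pool = balance_with_decoys(
            train, decoy_pool, seed=seed * 1000 + scheme_i * 2
        )
        test, decoy_pool = balance_with_decoys(
            test, decoy_pool, seed=seed * 1000 + scheme_i * 2 + 1
        )
        for split_name, frame in (("train", train), ("test", test)):
            sc[f"{split_name}_active"] = int((frame["label"] == "active").sum())
            sc[f"{split_name}_inactive"] = int((frame["label"] == "inactive").sum())
            sc[f"{split_name}_total"] = int(len(frame))
        report.counts[scheme.name] = sc
        pairs.append(
            DatasetPair(scheme, train.reset_index(drop=True), test.reset_index(drop=True))
        )
    return pairs, report


def write_dataset_csvs(pair: DatasetPair, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["std_key", "parent_smiles", "label", "source"]
    pair.train[cols].to_csv(out_dir / f"{pair.scheme.name}_train.csv", index=False)
    pair.test[cols].to_csv(out_dir / f"{pair.scheme.name}_test.csv", index=False)
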