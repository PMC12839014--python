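"""Molecular representations and Tanimoto similarity.

Seven encodings of a standardized compound are supported:

=========== ====== =====================================================
kind        length description
=========== ====== =====================================================
path_fp     1024   hashed subgraph-path (topological) fingerprint
morgan_fp   1024   radius-2 hashed circular fingerprint
dict_fp     881    substructure-key fingerprint from a versioned
                   dictionary (element counts, ring counts, SMARTS keys)
descriptors 208    physicochemical descriptors, min-max scaled to [0,1]
hybridRR    1232   path_fp ++ scaled descriptors
hybridMR    1232   morgan_fp ++ scaled descriptors
hybridPR    1089   dict_fp ++ scaled descriptors
=========== ====== =====================================================

Fingerprints are binary; descriptors are scaled with a min-max scaler
fitted on the training split only and clipped to [0,1] everywhere else,
so no information leaks from test or screening compounds into the
scaling.  The Tanimoto coefficient T = s/(a+b-s) compares two binary
fingerprints; its continuous (inner-product) generalization used by the
SVM kernel lives in :mod:`cdk9screen.models`.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from cdk9screen.standardize import REASON_UNPARSEABLE, StandardizationError

FP_KINDS = ("path_fp", "morgan_fp", "dict_fp")
HYBRID_PARTS = {"hybridRR": "path_fp", "hybridMR": "morgan_fp", "hybridPR": "dict_fp"}
KIND_LENGTHS = {
    "path_fp": 1024,
    "morgan_fp": 1024,
    "dict_fp": 881,
    "descriptors": 208,
    "hybridRR": 1232,
    "hybridMR": 1232,
    "hybridPR": 1089,
}
ALL_KINDS = tuple(KIND_LENGTHS)

_FP_SIZE = 1024
_MORGAN_RADIUS = 2


@dataclass(frozen=True)
class FeatureVector:
    kind: str
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in KIND_LENGTHS:
            raise ValueError(f"unknown feature kind: {self.kind}")
        if len(self.values) != KIND_LENGTHS[self.kind]:
            raise ValueError(
                f"{self.kind} expects length {KIND_LENGTHS[self.kind]}, "
                f"got {len(self.values)}"
            )


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(REASON_UNPARSEABLE, smiles)
    return mol


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _path_gen():
    return rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=_FP_SIZE)


@functools.lru_cache(maxsize=1)
def _morgan_gen():
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=_MORGAN_RADIUS, fpSize=_FP_SIZE
    )


def path_fp(smiles: str) -> FeatureVector:
    """1024-bit hashed atom-bond-path (subgraph) fingerprint."""
    arr = np.zeros(_FP_SIZE, dtype=np.uint8)
    fp = _path_gen().GetFingerprint(_mol(smiles))
    arr[list(fp.GetOnBits())] = 1
    return FeatureVector("path_fp", arr)


def morgan_fp(smiles: str) -> FeatureVector:
    """1024-bit radius-2 hashed circular-environment fingerprint."""
    arr = np.zeros(_FP_SIZE, dtype=np.uint8)
    fp = _morgan_gen().GetFingerprint(_mol(smiles))
    arr[list(fp.GetOnBits())] = 1
    return FeatureVector("morgan_fp", arr)


# ---------------------------------------------------------------------------
# Substructure-key fingerprint (881 keys from the versioned dictionary)
# ---------------------------------------------------------------------------

def _ring_feature_count(mol: Chem.Mol, size: int, kind: str) -> int:
    info = mol.GetRingInfo()
    count = 0
    for ring in info.AtomRings():
        if size and len(ring) != size:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        aromatic = all(a.GetIsAromatic() for a in atoms)
        symbols = {a.GetSymbol() for a in atoms}
        match kind:
            case "any":
                ok = True
            case "aromatic":
                ok = aromatic
            case "nonaromatic":
                ok = not aromatic
            case "carbocycle":
                ok = symbols == {"C"}
            case "hetero":
                ok = symbols != {"C"}
            case "N" | "O" | "S":
                ok = kind in symbols
            case _:
                raise ValueError(f"unknown ring kind {kind}")
        count += ok
    return count


@functools.lru_cache(maxsize=1)
def _load_keys():
    """Parse the shipped key dictionary into evaluator closures."""
    text = (
        resources.files("cdk9screen").joinpath("data/substructure_keys.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header, *rows = lines
    assert header.split("\t") == ["name", "kind", "param", "threshold"]
    evaluators = []
    for row in rows:
        name, kind, param, threshold = row.split("\t")
        t = int(threshold)
        if kind == "element_count":
            evaluators.append(
                (name, lambda m, sym=param, t=t: sum(
                    a.GetSymbol() == sym for a in m.GetAtoms()) >= t)
            )
        elif kind == "ring_count":
            parts = dict(p.split("=") for p in param.split(","))
            size, rkind = int(parts["size"]), parts["kind"]
            evaluators.append(
                (name, lambda m, s=size, k=rkind, t=t: _ring_feature_count(m, s, k) >= t)
            )
        elif kind == "smarts":
            patt = Chem.MolFromSmarts(param)
            if patt is None:
                raise ValueError(f"bad SMARTS in key dictionary: {param}")
            evaluators.append((name, lambda m, p=patt: m.HasSubstructMatch(p)))
        else:
            raise ValueError(f"unknown key kind {kind}")
    if len(evaluators) != KIND_LENGTHS["dict_fp"]:
        raise ValueError(
            f"key dictionary has {len(evaluators)} keys, "
            f"expected {KIND_LENGTHS['dict_fp']}"
        )
    return evaluators


def dict_fp(smiles: str) -> FeatureVector:
    """881-key substructure-dictionary fingerprint."""
    mol = _mol(smiles)
    arr = np.fromiter(
        (ev(mol) for _, ev in _load_keys()), dtype=np.uint8,
        count=KIND_LENGTHS["dict_fp"],
    )
    return FeatureVector("dict_fp", arr)


def key_names() -> list[str]:
    return [name for name, _ in _load_keys()]


# ---------------------------------------------------------------------------
# Physicochemical descriptors + min-max scaling
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def descriptor_names() -> tuple[str, ...]:
    text = (
        resources.files("cdk9screen")
        .joinpath("data/descriptor_manifest.txt")
        .read_text()
    )
    names = tuple(ln for ln in text.splitlines() if ln and not ln.startswith("#"))
    available = {n for n, _ in Descriptors._descList}
    missing = [n for n in names if n not in available]
    if missing or len(names) != KIND_LENGTHS["descriptors"]:
        raise RuntimeError(
            "descriptor manifest out of sync with the installed toolkit: "
            f"{len(names)} names, missing {missing[:5]}"
        )
    return names


@functools.lru_cache(maxsize=1)
def _descriptor_funcs():
    lookup = dict(Descriptors._descList)
    return [(n, lookup[n]) for n in descriptor_names()]


def descriptors(smiles: str) -> FeatureVector:
    """Raw (unscaled) values of the 208 manifest descriptors.

    Non-finite values are emitted as NaN here and imputed with the
    training median when the scaler is fitted/applied.
    """
    mol = _mol(smiles)
    vals = np.empty(KIND_LENGTHS["descriptors"], dtype=np.float64)
    for i, (_, func) in enumerate(_descriptor_funcs()):
        try:
            v = func(mol)
        except Exception:
            v = np.nan
        vals[i] = v if np.isfinite(v) else np.nan
    return FeatureVector("descriptors", vals)


@dataclass(frozen=True)
class ScalerModel:
    """Per-feature min-max affine transform learned from the training split."""

    data_min: np.ndarray
    data_max: np.ndarray
    median: np.ndarray  # training median, used to impute non-finite values

    def __post_init__(self):
        if np.any(self.data_max < self.data_min):
            raise ValueError("scaler max < min")


def fit_minmax(train: np.ndarray) -> ScalerModel:
    """Fit column-wise minima/maxima (NaN-aware) on the training matrix."""
    train = np.asarray(train, dtype=np.float64)
    with np.errstate(all="ignore"):
        median = np.nanmedian(train, axis=0)
    median = np.where(np.isfinite(median), median, 0.0)
    filled = np.where(np.isfinite(train), train, median)
    return ScalerModel(filled.min(axis=0), filled.max(axis=0), median)


def apply_minmax(scaler: ScalerModel, X: np.ndarray) -> np.ndarray:
    """Scale to [0,1]; out-of-range values clip; constant features map to 0."""
    X = np.asarray(X, dtype=np.float64)
    X = np.where(np.isfinite(X), X, scaler.median)
    span = scaler.data_max - scaler.data_min
    safe = np.where(span > 0, span, 1.0)
    scaled = (X - scaler.data_min) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    return np.clip(scaled, 0.0, 1.0)


def invert_minmax(scaler: ScalerModel, X: np.ndarray) -> np.ndarray:
    span = scaler.data_max - scaler.data_min
    return np.asarray(X, dtype=np.float64) * span + scaler.data_min


# ---------------------------------------------------------------------------
# Hybrids and matrix-level featurization
# ---------------------------------------------------------------------------

def hybrid(fp: FeatureVector, desc: FeatureVector) -> FeatureVector:
    """Concatenate a fingerprint with scaled descriptors, fingerprint first."""
    if desc.kind != "descriptors":
        raise ValueError(f"second argument must be descriptors, got {desc.kind}")
    for hkind, fkind in HYBRID_PARTS.items():
        if fp.kind == fkind:
            return FeatureVector(
                hkind, np.concatenate([fp.values.astype(np.float64), desc.values])
            )
    raise ValueError(f"first argument must be a fingerprint, got {fp.kind}")


_FP_FUNCS = {"path_fp": path_fp, "morgan_fp": morgan_fp, "dict_fp": dict_fp}


def featurize_matrix(
    smiles_list, kind: str, scaler: ScalerModel | None = None
) -> np.ndarray:
    """Feature matrix (n x length) for one representation.

    Hybrid and descriptor kinds require a fitted ``scaler``; fingerprint
    kinds ignore it.  Rows follow input order.
    """
    if kind in _FP_FUNCS:
        return np.vstack(
            [_FP_FUNCS[kind](s).values for s in smiles_list]
        ).astype(np.float64)
    raw = np.vstack([descriptors(s).values for s in smiles_list])
    if kind == "descriptors":
        if scaler is None:
            raise ValueError("descriptor featurization requires a fitted scaler")
        return apply_minmax(scaler, raw)
    if kind in HYBRID_PARTS:
        if scaler is None:
            raise ValueError("hybrid featurization requires a fitted scaler")
        fp_part = featurize_matrix(smiles_list, HYBRID_PARTS[kind])
        return np.hstack([fp_part, apply_minmax(scaler, raw)])
    raise ValueError(f"unknown feature kind: {kind}")


def fit_descriptor_scaler(train_smiles) -> ScalerModel:
    """Fit the min-max scaler on raw descriptors of the training compounds."""
    raw = np.vstack([descriptors(s).values for s in train_smiles])
    return fit_minmax(raw)


def manifest_hash() -> str:
    """Hash pinning the descriptor manifest + key dictionary versions."""
    h = hashlib.sha256()
    for name in descriptor_names():
        h.update(name.encode())
    for name, _ in _load_keys():
        h.update(name.encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tanimoto similarity (binary form)
# ---------------------------------------------------------------------------

def tanimoto(x: FeatureVector | np.ndarray, y: FeatureVector | np.ndarray) -> float:
    """T = s/(a+b-s) for two binary fingerprints of the same kind.

    ``s`` counts bits set in both vectors, ``a`` and ``b`` the bits set
    in each.  Defined as 0 when both vectors are all-zero.  Raises on
    non-binary input; continuous vectors use the kernel generalization
    in :mod:`cdk9screen.models`.
    """
    if isinstance(x, FeatureVector) and isinstance(y, FeatureVector):
        if x.kind != y.kind:
            raise ValueError(f"kind mismatch: {x.kind} vs {y.kind}")
        xv, yv = x.values, y.values
    else:
        xv = x.values if isinstance(x, FeatureVector) else np.asarray(x)
        yv = y.values if isinstance(y, FeatureVector) else np.asarray(y)
    if xv.shape != yv.shape:
        raise ValueError("length mismatch")
    if not (np.isin(xv, (0, 1)).all() and np.isin(yv, (0, 1)).all()):
        raise ValueError("tanimoto() is defined for binary fingerprints only")
    xv = xv.astype(np.int64)
    yv = yv.astype(np.int64)
    s = int((xv & yv).sum())
    a = int(xv.sum())
    b = int(yv.sum())
    denom = a + b - s
    return s / denom if denom else 0.0
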