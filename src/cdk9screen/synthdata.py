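"""Synthetic bioactivity data with a planted structure-activity signal.

The generator emulates the three inputs of a ligand-based screening
campaign — a ChEMBL-like activity table, a drug-like decoy library, and
a vendor screening library — without any download.  Compounds are
assembled from a fixed scaffold-decoration grammar (ring cores +
linkers + substituents), which makes the planted signal controllable: a
configurable fraction of compounds carry one of three distinctive
"pharmacophore" fragments, and potency is drawn from
Normal(mu_active, sigma) for carriers and Normal(mu_inactive, sigma)
otherwise.  Because the pharmacophores are fused heteroaromatics or a
sulfonyl-morpholine that the plain grammar can never produce, carrier
status is substructure-checkable and decoys are guaranteed
pharmacophore-free.

Realism knobs mirror the quirks of public bioactivity data: ~80% of
records are IC50 (the rest split over EC50/Ki/Kd), a fraction of weak
compounds are censored (">" relation at the censoring bound), some
entries are emitted as salts, and some compounds appear twice under
different activity types.  All output is a deterministic function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, RWMol
from rdkit.Chem.rdmolops import CombineMols

from cdk9screen.standardize import RawCompound, strip_to_parent

# ---------------------------------------------------------------------------
# Grammar: (smiles, attachment atom indices).  Attachment atoms must carry at
# least one hydrogen in every decorated product.
# ---------------------------------------------------------------------------

SCAFFOLDS = [
    ("c1ccccc1", (0, 2, 4)),          # benzene
    ("c1ccncc1", (0, 2)),             # pyridine
    ("c1cncnc1", (0, 3)),             # pyrimidine
    ("c1ccsc1", (0, 2)),              # thiophene
    ("c1ccoc1", (0, 2)),              # furan
    ("C1CCCCC1", (0, 2, 4)),          # cyclohexane
    ("C1CCNCC1", (0, 2)),             # piperidine (C-attached)
    ("c1ccc2ccccc2c1", (0, 5)),       # naphthalene
]

# two-point linkers: (smiles, head atom, tail atom); None = direct bond
LINKERS = [
    None,
    ("C", 0, 0),
    ("CC", 0, 1),
    ("O", 0, 0),
    ("CO", 0, 1),
    ("C(=O)", 0, 0),
]

# one-point substituents: (smiles, attachment atom)
SUBSTITUENTS = [
    ("C", 0), ("CC", 0), ("C(C)C", 0),
    ("F", 0), ("Cl", 0), ("Br", 0),
    ("O", 0), ("OC", 0), ("C#N", 0), ("C(F)(F)F", 0),
    ("c1ccccc1", 0), ("C1CCCCC1", 0),
]

# Planted pharmacophores: fragments the plain grammar cannot produce.
# (smiles, attachment atom on the fragment)
PHARMACOPHORES = [
    ("Nc1ncnc2ccccc12", 7),             # 4-aminoquinazoline, benzo CH
    ("Nc1nc2ccccc2s1", 5),              # 2-aminobenzothiazole, benzo CH
    ("S(=O)(=O)N1CCOCC1", 0),           # morpholine-4-sulfonyl, via S
]

SALT_SUFFIXES = [".Cl", ".Cl.Cl", ".OS(=O)(=O)O", ".OC(=O)C(=O)O"]

ACTIVITY_TYPES = ("IC50", "EC50", "Ki", "Kd")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic campaign.

    Potency means are on the pActivity scale (-log10 molar): carriers at
    8.0 (~10 nM, a typical potent-inhibitor series), plain compounds at
    4.5 (~32 uM), sigma 0.6, giving a (mu_active - mu_inactive)/sigma
    separation of ~5.8.  60% of library compounds carry a pharmacophore
    so that, after threshold labeling under either scheme, actives
    outnumber measured inactives and decoy balancing engages.
    """

    n_compounds: int = 1000
    seed: int = 0
    frac_ic50: float = 0.8
    frac_gt_relation: float = 0.10
    frac_salted: float = 0.10
    frac_duplicates: float = 0.05
    frac_pharmacophore: float = 0.60
    mu_active: float = 8.0
    mu_inactive: float = 4.5
    sigma: float = 0.6
    censor_bound_nm: float = 10_000.0  # "> 10 uM" censoring bound

    def __post_init__(self):
        for name in ("frac_ic50", "frac_gt_relation", "frac_salted",
                     "frac_duplicates", "frac_pharmacophore"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mu_active < self.mu_inactive:
            raise ValueError("mu_active must be >= mu_inactive")


@dataclass(frozen=True)
class SynthCompound:
    smiles: str
    has_pharmacophore: bool
    true_pactivity: float


def _pharmacophore_queries() -> list[Chem.Mol]:
    return [Chem.MolFromSmiles(s) for s, _ in PHARMACOPHORES]


def has_pharmacophore(smiles: str) -> bool:
    """Substructure check for any of the planted fragments."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(q) for q in _pharmacophore_queries())


def _attach(core: Chem.Mol, core_idx: int, frag_smiles: str, frag_idx: int) -> Chem.Mol:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = RWMol(CombineMols(core, frag))
    combo.AddBond(core_idx, core.GetNumAtoms() + frag_idx, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _build_compound(rng: np.random.Generator, with_pharmacophore: bool) -> str:
    scaffold_smiles, sites = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    mol = Chem.MolFromSmiles(scaffold_smiles)
    n_sub = int(rng.integers(1, min(3, len(sites)) + 1))
    chosen = list(rng.choice(len(sites), size=n_sub, replace=False))
    pharm_slot = int(rng.integers(n_sub)) if with_pharmacophore else -1
    for k, site_i in enumerate(chosen):
        site = sites[site_i]
        if k == pharm_slot:
            frag, fidx = PHARMACOPHORES[rng.integers(len(PHARMACOPHORES))]
            mol = _attach(mol, site, frag, fidx)
            continue
        linker = LINKERS[rng.integers(len(LINKERS))]
        sub, sidx = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        if linker is None:
            mol = _attach(mol, site, sub, sidx)
        else:
            lsmi, head, tail = linker
            n_before = mol.GetNumAtoms()
            mol = _attach(mol, site, lsmi, head)
            mol = _attach(mol, n_before + tail, sub, sidx)
    return Chem.MolToSmiles(mol)


def _std_key_of(smiles: str) -> str:
    return strip_to_parent(RawCompound("tmp", smiles)).std_key


def generate_library(cfg: SynthConfig) -> list[SynthCompound]:
    """Generate ``cfg.n_compounds`` distinct compounds with potencies.

    Distinctness is enforced on the standardized key, so no two library
    members collapse to the same parent structure downstream.
    """
    rng = np.random.default_rng(cfg.seed)
    compounds: list[SynthCompound] = []
    seen: set[str] = set()
    for _ in range(cfg.n_compounds):
        # the carrier flag is drawn once per emitted compound, so the
        # carrier count stays exactly Binomial(n, frac) regardless of how
        # often structure sampling collides with an earlier compound
        carrier = bool(rng.random() < cfg.frac_pharmacophore)
        for attempt in range(10_000):
            smiles = _build_compound(rng, carrier)
            key = _std_key_of(smiles)
            if key not in seen:
                break
        else:
            raise RuntimeError("grammar exhausted before reaching n_compounds")
        seen.add(key)
        mu = cfg.mu_active if carrier else cfg.mu_inactive
        p_act = float(rng.normal(mu, cfg.sigma))
        compounds.append(SynthCompound(smiles, carrier, p_act))
    return compounds


def assign_activities(compounds: list[SynthCompound], cfg: SynthConfig) -> pd.DataFrame:
    """Emit a ChEMBL-like activity table for the generated compounds.

    Columns: compound_id, smiles, activity_type, relation, value, units.
    Weak compounds (true potency below the censoring bound) have a
    ``frac_gt_relation`` chance of being reported as "> bound" instead of
    an exact value; a ``frac_duplicates`` subset gains a second row under
    a different activity type; a ``frac_salted`` subset is emitted as a
    salt form.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    censor_p = 9.0 - np.log10(cfg.censor_bound_nm)  # bound on pActivity scale
    other_types = [t for t in ACTIVITY_TYPES if t != "IC50"]
    rows = []
    for i, comp in enumerate(compounds):
        cid = f"SYN{i:06d}"
        smiles = comp.smiles
        if rng.random() < cfg.frac_salted:
            smiles = smiles + SALT_SUFFIXES[rng.integers(len(SALT_SUFFIXES))]
        if rng.random() < cfg.frac_ic50:
            a_type = "IC50"
        else:
            a_type = other_types[rng.integers(len(other_types))]

        censored = (
            comp.true_pactivity <= censor_p
            and rng.random() < cfg.frac_gt_relation
        )
        if censored:
            relation, value_nm = ">", cfg.censor_bound_nm
        else:
            relation, value_nm = "=", 10.0 ** (9.0 - comp.true_pactivity)

        if rng.random() < 0.3:  # report some records in micromolar
            rows.append((cid, smiles, a_type, relation, value_nm / 1000.0, "uM"))
        else:
            rows.append((cid, smiles, a_type, relation, value_nm, "nM"))

        if relation == "=" and rng.random() < cfg.frac_duplicates:
            dup_type = other_types[rng.integers(len(other_types))]
            jitter = 10.0 ** (9.0 - (comp.true_pactivity + rng.normal(0, 0.1)))
            rows.append((cid, smiles, dup_type, "=", jitter, "nM"))
    return pd.DataFrame(
        rows,
        columns=["compound_id", "smiles", "activity_type", "relation", "value", "units"],
    )


def _druglike(mol: Chem.Mol) -> bool:
    return (
        200.0 <= Descriptors.MolWt(mol) <= 500.0
        and Descriptors.NumHDonors(mol) <= 5
        and Descriptors.NumHAcceptors(mol) <= 10
    )


def generate_decoys(
    n: int, seed: int, exclude_keys: set[str] | None = None
) -> list[str]:
    """Drug-like, pharmacophore-free decoy SMILES (presumed inactive).

    Every decoy passes MW 200-500, <=5 H-bond donors, <=10 acceptors, has
    a unique standardized key, and matches none of the planted
    pharmacophore fragments.  ``exclude_keys`` bars overlap with e.g. the
    activity-table compounds.
    """
    rng = np.random.default_rng(seed)
    exclude = set(exclude_keys or ())
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 500 * max(n, 10)
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("decoy sampling exhausted")
        smiles = _build_compound(rng, with_pharmacophore=False)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or not _druglike(mol):
            continue
        key = _std_key_of(smiles)
        if key in seen or key in exclude:
            continue
        seen.add(key)
        out.append(smiles)
    return out


def generate_screening_library(
    n: int,
    seed: int,
    frac_pharmacophore: float = 0.02,
    unavailable_frac: float = 0.2,
) -> pd.DataFrame:
    """A vendor-catalogue stand-in: mostly plain compounds, a few carriers.

    Returns columns compound_id, smiles, available.  A fraction of
    entries is flagged commercially unavailable so that representative
    selection has to skip them, as happens with real catalogues.
    """
    rng = np.random.default_rng(seed)
    rows = []
    seen: set[str] = set()
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > 500 * max(n, 10):
            raise RuntimeError("screening library sampling exhausted")
        carrier = bool(rng.random() < frac_pharmacophore)
        smiles = _build_compound(rng, carrier)
        if smiles in seen:
            continue
        seen.add(smiles)
        rows.append(
            (f"LIB{len(rows):07d}", smiles, bool(rng.random() >= unavailable_frac))
        )
    return pd.DataFrame(rows, columns=["compound_id", "smiles", "available"])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_activity_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_smi(path: str | Path, smiles_list, prefix: str = "CMPD") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(smiles_list):
            fh.write(f"{s} {prefix}{i:06d}\n")
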