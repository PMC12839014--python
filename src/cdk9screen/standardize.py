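"""Chemical structure standardization.

Every compound entering the pipeline — training, test, decoy or screening
library — passes through the same protocol: salt stripping to the parent
fragment, assignment of the dominant ionization state at physiological pH
(7.4) by an explicit rule table, and canonicalization to a deterministic
SMILES key used for deduplication and train/test overlap control.

The ionization rules cover the groups that dominate drug-like chemistry:

* deprotonated: carboxylic, sulfonic and phosphonic acids, tetrazoles
* protonated: aliphatic primary/secondary/tertiary amines, amidines,
  guanidines
* left neutral: anilines, amides, sulfonamides, aromatic N-heterocycles

The transform is idempotent: a group that has already been charged no
longer matches its neutral-form pattern.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

# Reject reason codes (never silently drop a record)
REASON_EMPTY = "empty_smiles"
REASON_UNPARSEABLE = "unparseable_smiles"
REASON_NO_ATOMS = "no_atoms"


class StandardizationError(ValueError):
    """Raised when a compound cannot be standardized; carries a reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class RawCompound:
    """A compound as supplied: an opaque identifier and a SMILES string."""

    compound_id: str
    smiles: str


@dataclass(frozen=True)
class StdCompound:
    """A standardized compound.

    ``parent_smiles`` is the canonical SMILES of the retained parent
    fragment after ionization; ``std_key`` is the canonical,
    ionization-normalized SMILES used as the deduplication identity.
    For this protocol the two coincide; ``std_key`` is kept as a separate
    field so the identity contract survives future protocol changes.
    """

    compound_id: str
    parent_smiles: str
    std_key: str
    n_fragments_removed: int = 0


# ---------------------------------------------------------------------------
# Ionization rule table (pH 7.4).  Each rule: SMARTS, index of the atom whose
# charge changes within the match, and the action.  Neutral-form constraints
# (+0, explicit H counts) make every rule a no-op on its own output.
# ---------------------------------------------------------------------------

_DEPROTONATE = [
    # carboxylic acid -> carboxylate (pKa ~4)
    ("[CX3](=O)[OX2H1]", 2),
    # sulfonic acid -> sulfonate (pKa ~ -1)
    ("[SX4](=O)(=O)[OX2H1]", 3),
    # tetrazole NH (pKa ~4.9), both common tautomers
    ("[nX3H1]1nnnc1", 0),
    ("[nX3H1]1nncn1", 0),
]

# Phosphonic/phosphoric acids: remove one proton only (first pKa ~2, the
# second sits near 7.4, so the mono-anion is the representative species).
# Centers already carrying an anionic oxygen are skipped, keeping the
# transform idempotent.
_DEPROTONATE_ONE_PER_CENTER = [
    ("[PX4;!$(P[O-])](=O)[OX2H1]", 0, 2),  # (pattern, center atom, acidic O)
]

_PROTONATE = [
    # aliphatic amine (primary/secondary/tertiary) -> ammonium (pKa ~10).
    # Excludes amides/sulfonamides/etc (N bonded to a non-carbon heavy
    # atom), anilines (N on an aromatic atom), amidine/enamine nitrogens
    # (N on an sp2 carbon), and anything already charged.
    ("[NX3;+0;!$([N]-[!#6;!#1]);!$([N]-[c,n]);!$([N]-[CX3]=[O,S,N,C])]", 0),
    # amidines and guanidines: protonate the imino nitrogen (pKa ~12)
    ("[NX2;+0]=[CX3;!$([C]=[O,S]);!$([C]-[O,S])][NX3;+0]", 0),
]


def _apply_charge(mol: Chem.RWMol, idx: int, delta: int) -> None:
    atom = mol.GetAtomWithIdx(idx)
    atom.SetFormalCharge(atom.GetFormalCharge() + delta)
    n_h = atom.GetTotalNumHs() + delta
    atom.SetNumExplicitHs(max(n_h, 0))
    atom.SetNoImplicit(True)


def ionize_ph74(parent_smiles: str) -> str:
    """Assign pH-7.4 charge states by the documented rule table.

    Returns the canonical SMILES of the ionized species.  Idempotent:
    applying the transform to its own output is the identity.
    """
    mol = Chem.MolFromSmiles(parent_smiles)
    if mol is None:
        raise StandardizationError(REASON_UNPARSEABLE, parent_smiles)
    rw = Chem.RWMol(mol)

    to_deprotonate: set[int] = set()
    for smarts, pos in _DEPROTONATE:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            to_deprotonate.add(match[pos])
    for smarts, center_pos, acid_pos in _DEPROTONATE_ONE_PER_CENTER:
        patt = Chem.MolFromSmarts(smarts)
        per_center: dict[int, int] = {}
        for match in rw.GetSubstructMatches(patt):
            center, acid = match[center_pos], match[acid_pos]
            per_center.setdefault(center, acid)
            per_center[center] = min(per_center[center], acid)
        to_deprotonate.update(per_center.values())

    to_protonate: set[int] = set()
    for smarts, pos in _PROTONATE:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            to_protonate.add(match[pos])
    # a site cannot be both; acids win (zwitterions keep both changes)
    to_protonate -= to_deprotonate

    for idx in to_deprotonate:
        _apply_charge(rw, idx, -1)
    for idx in to_protonate:
        _apply_charge(rw, idx, +1)

    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _fragment_sort_key(frag: Chem.Mol) -> tuple[int, float, str]:
    return (
        -frag.GetNumHeavyAtoms(),
        -Descriptors.MolWt(frag),
        Chem.MolToSmiles(frag),
    )


def strip_to_parent(raw: RawCompound) -> StdCompound:
    """Standardize one compound: salt strip, ionize, canonicalize.

    The parent is the fragment with the most heavy atoms; ties break by
    molecular weight, then by lexicographically smallest canonical SMILES.
    Raises :class:`StandardizationError` with a reason code on failure.
    """
    smiles = raw.smiles.strip() if raw.smiles else ""
    if not smiles:
        raise StandardizationError(REASON_EMPTY, raw.compound_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(REASON_UNPARSEABLE, smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise StandardizationError(REASON_NO_ATOMS, smiles)
    parent = min(frags, key=_fragment_sort_key)
    parent_smiles = ionize_ph74(Chem.MolToSmiles(parent))
    return StdCompound(
        compound_id=raw.compound_id,
        parent_smiles=parent_smiles,
        std_key=make_std_key(parent_smiles),
        n_fragments_removed=len(frags) - 1,
    )


def make_std_key(parent_smiles: str) -> str:
    """Canonical SMILES identity of a standardized structure.

    Two inputs describing the same standardized structure (any atom
    ordering or SMILES spelling) map to the same key.  Stereochemistry is
    retained, so enantiomers stay distinct.
    """
    mol = Chem.MolFromSmiles(parent_smiles)
    if mol is None:
        raise StandardizationError(REASON_UNPARSEABLE, parent_smiles)
    return Chem.MolToSmiles(mol)


def standardize_all(
    raws: Iterable[RawCompound],
) -> tuple[list[StdCompound], list[tuple[str, str]]]:
    """Standardize a batch; returns (standardized, rejects).

    Rejects are (compound_id, reason_code) pairs — records are never
    silently dropped.
    """
    out: list[StdCompound] = []
    rejects: list[tuple[str, str]] = []
    for raw in raws:
        try:
            out.append(strip_to_parent(raw))
        except StandardizationError as err:
            rejects.append((raw.compound_id, err.reason))
    return out, rejects


# ---------------------------------------------------------------------------
# I/O: CSV, .smi (whitespace-delimited SMILES + id) and SDF readers, plus the
# standardized-output and reject-log writers.
# ---------------------------------------------------------------------------

def read_compounds(
    path: str | Path,
    smiles_col: str = "smiles",
    id_col: str = "compound_id",
) -> list[RawCompound]:
    """Read raw compounds from .csv, .smi or .sdf by file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        raws = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                raws.append(RawCompound(str(row[id_col]), row[smiles_col]))
        return raws
    if suffix == ".smi":
        raws = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                cid = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
                raws.append(RawCompound(cid, parts[0]))
        return raws
    if suffix == ".sdf":
        raws = []
        for i, mol in enumerate(Chem.SDMolSupplier(str(path), sanitize=True)):
            if mol is None:
                raws.append(RawCompound(f"{path.stem}_{i}", ""))
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{i}"
            raws.append(RawCompound(cid, Chem.MolToSmiles(mol)))
        return raws
    raise ValueError(f"unsupported compound file extension: {suffix}")


def write_standardized(path: str | Path, compounds: Sequence[StdCompound]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "parent_smiles", "std_key"])
        for c in compounds:
            writer.writerow([c.compound_id, c.parent_smiles, c.std_key])


def write_reject_log(path: str | Path, rejects: Sequence[tuple[str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "reason"])
        writer.writerows(rejects)
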