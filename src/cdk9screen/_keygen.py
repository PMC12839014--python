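"""Generator for the 881-key substructure dictionary.

The dictionary is a package convention, versioned through the shipped
``data/substructure_keys.tsv`` file.  It mixes three key classes in a
fixed priority order — element count thresholds, ring count thresholds,
and SMARTS substructure patterns (curated functional groups, then bonded
element pairs, then bonded triples) — and truncates the deterministic
candidate sequence at exactly 881 entries.

Regenerate the data file with ``python -m cdk9screen._keygen``.
"""

from __future__ import annotations

from pathlib import Path

N_KEYS = 881
KEY_VERSION = "1"

_COUNTED_ELEMENTS = [
    ("C", [1, 2, 4, 8, 16, 24, 32]),
    ("N", [1, 2, 3, 4, 6, 8]),
    ("O", [1, 2, 3, 4, 6, 8, 12]),
    ("S", [1, 2, 3, 4]),
    ("P", [1, 2]),
    ("F", [1, 2, 4, 8]),
    ("Cl", [1, 2, 3, 4]),
    ("Br", [1, 2, 3]),
    ("I", [1, 2]),
    ("B", [1, 2]),
    ("Si", [1]),
]

_RARE_ELEMENTS = [
    "Se", "Li", "Na", "K", "Mg", "Ca", "Fe", "Zn", "Cu", "Mn", "Co", "Ni",
    "As", "Al", "Sn", "Ag", "Au", "Hg", "Pt", "Pd", "Ti", "Cr", "Sb", "Ba",
    "Bi", "Gd", "Ge", "Te", "Tl", "Pb",
]

_RING_KINDS = ["any", "aromatic", "nonaromatic", "carbocycle", "hetero", "N", "O", "S"]
_RING_THRESHOLDS = {3: [1, 2], 4: [1, 2], 5: [1, 2, 3, 4, 5], 6: [1, 2, 3, 4, 5],
                    7: [1, 2], 8: [1, 2], 9: [1], 10: [1]}

_FUNCTIONAL_GROUPS = [
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("carboxylate", "[CX3](=O)[O-]"),
    ("ester", "[CX3](=O)[OX2][#6]"),
    ("amide", "[CX3](=O)[NX3]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("aldehyde", "[CX3H1]=O"),
    ("ether", "[#6][OX2][#6]"),
    ("hydroxyl", "[OX2H]"),
    ("phenol", "[OX2H][c]"),
    ("primary_amine", "[NX3;H2;!$(N=*)][#6]"),
    ("secondary_amine", "[NX3;H1]([#6])[#6]"),
    ("tertiary_amine", "[NX3]([#6])([#6])[#6]"),
    ("ammonium", "[N+]"),
    ("aniline_n", "[NX3][c]"),
    ("nitrile", "[CX2]#[NX1]"),
    ("nitro", "[NX3](=O)[OX1]"),
    ("azo", "[#6][NX2]=[NX2][#6]"),
    ("hydrazine", "[NX3][NX3]"),
    ("oxime", "[CX3]=[NX2][OX2H]"),
    ("imine", "[CX3]=[NX2]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("urea", "[NX3][CX3](=O)[NX3]"),
    ("carbamate", "[NX3][CX3](=O)[OX2]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("sulfone", "[#6][SX4](=O)(=O)[#6]"),
    ("sulfoxide", "[#6][SX3](=O)[#6]"),
    ("sulfonic", "[SX4](=O)(=O)[OX2H,OX1-]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[#6][SX2][#6]"),
    ("thiourea", "[NX3][CX3](=S)[NX3]"),
    ("thiocarbonyl", "[CX3]=[SX1]"),
    ("phosphate", "[PX4](=O)([OX2,OX1-])([OX2,OX1-])"),
    ("halomethyl", "[CX4][F,Cl,Br,I]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("aryl_halide", "[c][F,Cl,Br,I]"),
    ("vinyl", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("allyl", "[CX4][CX3]=[CX3]"),
    ("benzyl", "[CX4][c]"),
    ("biphenyl", "c1ccccc1-c1ccccc1"),
    ("tetrazole", "c1nnn[n]1"),
    ("imidazole", "c1cnc[n]1"),
    ("pyridine_ring", "c1ccncc1"),
    ("pyrimidine_ring", "c1cncnc1"),
    ("furan_ring", "c1ccoc1"),
    ("thiophene_ring", "c1ccsc1"),
    ("morpholine_ring", "C1COCCN1"),
    ("piperazine_ring", "C1CNCCN1"),
    ("piperidine_ring", "C1CCNCC1"),
    ("naphthalene_ring", "c1ccc2ccccc2c1"),
]

_PAIR_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si"]
_DOUBLE_ELEMENTS = ["C", "N", "O", "S", "P"]
_AROMATIC_ELEMENTS = ["c", "n", "o", "s"]
_TRIPLE_CENTERS = ["C", "N", "O", "S", "P"]

_ATNUM = {"C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "F": 9, "Cl": 17,
          "Br": 35, "I": 53, "B": 5, "Si": 14,
          "c": 6, "n": 7, "o": 8, "s": 16}


def _atom(sym: str) -> str:
    if sym in ("c", "n", "o", "s"):
        return f"[{sym}]"
    return f"[#{_ATNUM[sym]}]"


def build_keys() -> list[tuple[str, str, str, str]]:
    """Return the ordered key table as (name, kind, param, threshold) rows."""
    keys: list[tuple[str, str, str, str]] = []
    for sym, thresholds in _COUNTED_ELEMENTS:
        for t in thresholds:
            keys.append((f"E_{sym}_ge{t}", "element_count", sym, str(t)))
    for sym in _RARE_ELEMENTS:
        keys.append((f"E_{sym}_ge1", "element_count", sym, "1"))

    for t in range(1, 7):
        keys.append((f"R_total_ge{t}", "ring_count", "size=0,kind=any", str(t)))
    for t in range(1, 7):
        keys.append((f"R_aromatic_ge{t}", "ring_count", "size=0,kind=aromatic", str(t)))
    for size in range(3, 11):
        for kind in _RING_KINDS:
            for t in _RING_THRESHOLDS[size]:
                keys.append((f"R_{kind}{size}_ge{t}", "ring_count",
                             f"size={size},kind={kind}", str(t)))

    for name, smarts in _FUNCTIONAL_GROUPS:
        keys.append((f"F_{name}", "smarts", smarts, "1"))

    n = len(_PAIR_ELEMENTS)
    for bond, tag in (("~", "a"), ("-", "s")):
        for i in range(n):
            for j in range(i, n):
                x, y = _PAIR_ELEMENTS[i], _PAIR_ELEMENTS[j]
                keys.append((f"P_{tag}_{x}{y}", "smarts",
                             f"{_atom(x)}{bond}{_atom(y)}", "1"))
    for i in range(len(_DOUBLE_ELEMENTS)):
        for j in range(i, len(_DOUBLE_ELEMENTS)):
            x, y = _DOUBLE_ELEMENTS[i], _DOUBLE_ELEMENTS[j]
            keys.append((f"P_d_{x}{y}", "smarts", f"{_atom(x)}={_atom(y)}", "1"))
    for x, y in (("C", "C"), ("C", "N"), ("N", "N")):
        keys.append((f"P_t_{x}{y}", "smarts", f"{_atom(x)}#{_atom(y)}", "1"))
    for i in range(len(_AROMATIC_ELEMENTS)):
        for j in range(i, len(_AROMATIC_ELEMENTS)):
            x, y = _AROMATIC_ELEMENTS[i], _AROMATIC_ELEMENTS[j]
            keys.append((f"P_ar_{x}{y}", "smarts", f"{_atom(x)}:{_atom(y)}", "1"))

    for center in _TRIPLE_CENTERS:
        for i in range(n):
            for j in range(i, n):
                x, y = _PAIR_ELEMENTS[i], _PAIR_ELEMENTS[j]
                keys.append((f"T_{x}{center}{y}", "smarts",
                             f"{_atom(x)}~{_atom(center)}~{_atom(y)}", "1"))
    for center in ("C", "N"):
        for i in range(n):
            for j in range(i, n):
                x, y = _PAIR_ELEMENTS[i], _PAIR_ELEMENTS[j]
                keys.append((f"Ts_{x}{center}{y}", "smarts",
                             f"{_atom(x)}-{_atom(center)}-{_atom(y)}", "1"))

    if len(keys) < N_KEYS:
        raise RuntimeError(f"candidate key list too short: {len(keys)}")
    return keys[:N_KEYS]


def write_tsv(path: str | Path) -> None:
    rows = build_keys()
    with open(path, "w") as fh:
        fh.write(f"# substructure key dictionary v{KEY_VERSION}\n")
        fh.write("name\tkind\tparam\tthreshold\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


if __name__ == "__main__":
    out = Path(__file__).parent / "data" / "substructure_keys.tsv"
    out.parent.mkdir(exist_ok=True)
    write_tsv(out)
    print(f"wrote {out} ({len(build_keys())} keys)")
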