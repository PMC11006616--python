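"""Regenerate the packaged idealized-geometry table.

Derives an internal-coordinate (NeRF-style) atom tree for every standard
amino acid and ribonucleotide from the Chemical Component Dictionary ideal
coordinates bundled with biotite, and writes it to
src/cryoident/data/ideal_geometry.json.

Run from the repository root:  python scripts/make_geometry_table.py
"""

from __future__ import annotations

import json
from collections import deque
from pathlib import Path

import numpy as np
import biotite.structure.info as info

AMINO = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
NUCLEOTIDE = ["A", "C", "G", "U"]

# Leaving/terminal atoms not part of a polymerized residue.
EXCLUDE = {"OXT", "OP3", "HXT", "HOP3"}

CHI_DEFS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    # PRO ring closure: chi rotation would break the ring; torsions kept fixed.
    "PRO": [],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [],
    # Glycosidic torsion chi about C1'-N9 (purines) / C1'-N1 (pyrimidines).
    "A": [("O4'", "C1'", "N9", "C4")],
    "G": [("O4'", "C1'", "N9", "C4")],
    "C": [("O4'", "C1'", "N1", "C2")],
    "U": [("O4'", "C1'", "N1", "C2")],
}


def _angle(a, b, c):
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def build_entry(res_id: str, polymer: str) -> dict:
    arr = info.residue(res_id)
    keep = (arr.element != "H") & ~np.isin(arr.atom_name, list(EXCLUDE))
    idx_keep = np.where(keep)[0]
    names = list(arr.atom_name[idx_keep])
    coords = {n: arr.coord[i].astype(float) for n, i in zip(names, idx_keep)}
    elements = {n: str(arr.element[i]) for n, i in zip(names, idx_keep)}

    adj = {n: set() for n in names}
    for i, j, _ in arr.bonds.as_array():
        ni, nj = arr.atom_name[i], arr.atom_name[j]
        if ni in adj and nj in adj:
            adj[ni].add(nj)
            adj[nj].add(ni)

    if polymer == "amino":
        frame = ["CA", "C", "N"]
    else:
        frame = ["P", "O5'", "C5'"]
    root, f1, f2 = frame

    # BFS tree rooted at the frame origin; frame atoms first.
    parent: dict[str, str | None] = {root: None}
    order = [root]
    queue = deque([root])
    while queue:
        cur = queue.popleft()
        for nb in sorted(adj[cur]):
            if nb not in parent:
                parent[nb] = cur
                order.append(nb)
                queue.append(nb)
    assert set(order) == set(names), (res_id, set(names) - set(order))

    # Local frame: origin at root, x along root->f1, f2 in the xy-plane (+y).
    ex = coords[f1] - coords[root]
    ex /= np.linalg.norm(ex)
    v = coords[f2] - coords[root]
    ey = v - np.dot(v, ex) * ex
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    rot = np.stack([ex, ey, ez])

    def local(n):
        return [round(float(x), 5) for x in rot @ (coords[n] - coords[root])]

    chis = CHI_DEFS[res_id]
    chi_values = [round(_dihedral(*(coords[a] for a in q)), 3) for q in chis]
    chi_axes = {(q[1], q[2]): k for k, q in enumerate(chis)}

    atoms = []
    for name in order:
        if name in frame:
            continue
        p = parent[name]
        g = parent[p]
        if g is None:  # p is the root
            g, t = f1, f2
        else:
            t = parent[g]
            if t is None:  # g is the root
                t = f1 if p != f1 else f2
        tors = _dihedral(coords[t], coords[g], coords[p], coords[name])
        rec = {
            "name": name,
            "element": elements[name],
            "refs": [t, g, p],
            "bond": round(float(np.linalg.norm(coords[name] - coords[p])), 4),
            "angle": round(_angle(coords[g], coords[p], coords[name]), 3),
        }
        k = chi_axes.get((g, p))
        if k is not None:
            rec["chi"] = k
            rec["offset"] = round(tors - chi_values[k], 3)
        else:
            rec["torsion"] = round(tors, 3)
        atoms.append(rec)

    return {
        "polymer": polymer,
        "frame_atoms": frame,
        "frame_coords": [local(n) for n in frame],
        "frame_elements": [elements[n] for n in frame],
        "atoms": atoms,
        "chi_atoms": [list(q) for q in chis],
        "chi_ideal": chi_values,
    }


def main():
    table = {}
    for r in AMINO:
        table[r] = build_entry(r, "amino")
    for r in NUCLEOTIDE:
        table[r] = build_entry(r, "nucleotide")
    out = Path(__file__).resolve().parents[1] / "src" / "cryoident" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "ideal_geometry.json"
    path.write_text(json.dumps(table, indent=None, separators=(",", ":")) + "\n")
    n_atoms = sum(len(v["atoms"]) + 3 for v in table.values())
    print(f"wrote {path} ({len(table)} residues, {n_atoms} atoms, "
          f"{path.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
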