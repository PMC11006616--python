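"""Vector geometry helpers and the idealized internal-coordinate tables.

The packaged table (``data/ideal_geometry.json``) stores, for each of the 20
amino acids and 4 ribonucleotides, an atom tree rooted at the residue's
backbone frame: every heavy atom beyond the three frame atoms is defined by a
bond length to its parent, a bond angle, and a torsion that is either fixed
or tied to one of the residue's rotatable torsions (side-chain chi angles, or
the glycosidic torsion for bases). Atoms are reconstructed by the standard
NeRF (natural extension reference frame) placement.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "bond_angle", "dihedral", "place_atom", "geometry_table",
    "IdealGeometryTable",
]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray,
             d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def place_atom(t: np.ndarray, g: np.ndarray, p: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom at distance ``bond`` from ``p``, with angle g-p-new
    and torsion t-g-p-new (degrees) — NeRF construction."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the (g, p) internal frame
    d = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    bc = p - g
    bc /= np.linalg.norm(bc)
    n = np.cross(g - t, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return p + m @ d


class IdealGeometryTable:
    """Idealized residue geometry: frame-atom local coordinates plus the
    internal-coordinate tree for every remaining heavy atom."""

    def __init__(self, data: dict):
        self._data = data

    def __contains__(self, residue_name: str) -> bool:
        return residue_name in self._data

    def entry(self, residue_name: str) -> dict:
        try:
            return self._data[residue_name]
        except KeyError:
            raise KeyError(
                f"no idealized geometry for residue {residue_name!r}"
            ) from None

    def residue_names(self) -> list[str]:
        return list(self._data)

    def chi_names(self, residue_name: str) -> list[str]:
        """Names of the rotatable torsions of a residue, in order
        (``chi1``..``chi4`` for side chains, ``chi`` for the base)."""
        e = self.entry(residue_name)
        n = len(e["chi_atoms"])
        if e["polymer"] == "nucleotide":
            return ["chi"][:n]
        return [f"chi{i + 1}" for i in range(n)]

    def chi_ideal(self, residue_name: str) -> dict[str, float]:
        e = self.entry(residue_name)
        return dict(zip(self.chi_names(residue_name), e["chi_ideal"]))

    def bond_length(self, residue_name: str, a: str, b: str) -> float:
        """Tabulated ideal length of the a-b bond (order-insensitive)."""
        for rec in self.entry(residue_name)["atoms"]:
            if {rec["name"], rec["refs"][2]} == {a, b}:
                return rec["bond"]
        e = self.entry(residue_name)
        fa = e["frame_atoms"]
        fc = np.asarray(e["frame_coords"])
        if a in fa and b in fa:
            return float(np.linalg.norm(fc[fa.index(a)] - fc[fa.index(b)]))
        raise KeyError(f"{residue_name}: no tabulated bond {a}-{b}")


@lru_cache(maxsize=1)
def geometry_table() -> IdealGeometryTable:
    """The packaged idealized-geometry table (cached)."""
    text = (
        resources.files("cryoident") / "data" / "ideal_geometry.json"
    ).read_text()
    return IdealGeometryTable(json.loads(text))
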