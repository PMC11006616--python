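"""Atomic-model data structures, coordinate I/O and full-atom generation.

The central objects are :class:`ResiduePrediction` — one predicted residue
(position, orientation frame, identity probabilities, confidence) — and
:class:`AtomicModel`, an ordered chain/residue/atom hierarchy. Per-residue
confidence scores, derived from the predicted backbone r.m.s.d. by a linear
map between 1.2 and 0.5 Å, travel in the B-factor column of written
coordinate files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import gemmi

from . import alphabets
from .geometry import geometry_table, place_atom, dihedral

__all__ = [
    "Atom", "Residue", "Chain", "AtomicModel", "ResiduePrediction",
    "confidence_score", "build_full_atoms", "measure_torsions",
    "read_model", "write_model", "read_predictions", "write_predictions",
    "RMSD_BEST", "RMSD_WORST",
]

# Anchors of the linear confidence mapping: predicted backbone r.m.s.d. of
# 0.5 Å (or better) scores 1, 1.2 Å (or worse) scores 0.
RMSD_BEST = 0.5
RMSD_WORST = 1.2


def confidence_score(predicted_rmsd):
    """Map a predicted backbone r.m.s.d. (Å) to a confidence in [0, 1].

    Linear between ``RMSD_WORST`` (score 0) and ``RMSD_BEST`` (score 1),
    clamped outside that range. Accepts scalars or arrays.
    """
    r = np.asarray(predicted_rmsd, dtype=float)
    if np.any(r < 0):
        raise ValueError("predicted r.m.s.d. must be non-negative")
    score = np.clip((RMSD_WORST - r) / (RMSD_WORST - RMSD_BEST), 0.0, 1.0)
    return float(score) if np.isscalar(predicted_rmsd) else score


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)


@dataclass
class Residue:
    seq_id: int
    identity: str  # one-letter code, or 'X' for unknown
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.seq_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def anchor(self) -> np.ndarray:
        """CA (amino) or P (nucleotide) position; first atom as fallback."""
        for name in ("CA", "P"):
            if self.has_atom(name):
                return self.atom(name).coord
        return self.atoms[0].coord


@dataclass
class Chain:
    chain_id: str
    polymer: str  # 'amino' | 'nucleotide'
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue numbers not strictly "
                "increasing"
            )

    def __len__(self):
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.identity for r in self.residues)


@dataclass
class AtomicModel:
    chains: list[Chain] = field(default_factory=list)

    def __len__(self):
        return len(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def all_residues(self):
        for c in self.chains:
            for r in c.residues:
                yield c, r


@dataclass
class ResiduePrediction:
    """One predicted residue: backbone anchor position (CA or P, Å), local
    orientation frame, identity probabilities over the polymer alphabet,
    confidence c in [0, 1] and the predicted backbone r.m.s.d. it derives
    from, plus predicted rotatable torsions (degrees)."""

    position: np.ndarray
    frame: np.ndarray
    identity_probs: np.ndarray
    confidence: float
    predicted_rmsd: float = 0.0
    torsions: dict = field(default_factory=dict)
    polymer_class: str = "amino"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.frame = np.asarray(self.frame, dtype=float).reshape(3, 3)
        self.identity_probs = np.asarray(self.identity_probs, dtype=float)
        n = len(alphabets.letters(self.polymer_class))
        if self.identity_probs.shape != (n,):
            raise ValueError(
                f"identity_probs must have length {n} for "
                f"{self.polymer_class} residues"
            )
        if np.any(self.identity_probs < 0) or \
                abs(self.identity_probs.sum() - 1.0) > 1e-6:
            raise ValueError("identity_probs must be a probability simplex")
        if abs(np.linalg.det(self.frame) - 1.0) > 1e-6:
            raise ValueError("frame must be a proper rotation (det = +1)")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.predicted_rmsd < 0:
            raise ValueError("predicted_rmsd must be non-negative")

    @property
    def argmax_identity(self) -> str:
        letters = alphabets.letters(self.polymer_class)
        return letters[int(np.argmax(self.identity_probs))]


# Conventional leading atom order for output files.
_BACKBONE_FIRST = {
    "amino": ["N", "CA", "C", "O"],
    "nucleotide": ["P", "OP1", "OP2", "O5'", "C5'"],
}


def build_full_atoms(pred: ResiduePrediction, identity: str,
                     seq_id: int = 1) -> Residue:
    """Generate all heavy atoms of a residue from its predicted position,
    orientation frame and torsion angles, using idealized geometry.

    Backbone frame atoms are placed directly from the frame; every other
    atom follows by internal-coordinate construction. A missing rotatable
    torsion falls back to the table's canonical value with a warning.
    """
    table = geometry_table()
    name3 = alphabets.residue_name(identity, pred.polymer_class)
    entry = table.entry(name3)
    if entry["polymer"] != pred.polymer_class:
        raise ValueError(
            f"{identity!r} is not a {pred.polymer_class} residue"
        )

    pos: dict[str, np.ndarray] = {}
    order: list[str] = []
    elements: dict[str, str] = {}
    for name, local, elem in zip(entry["frame_atoms"],
                                 entry["frame_coords"],
                                 entry["frame_elements"]):
        pos[name] = pred.position + pred.frame @ np.asarray(local)
        elements[name] = elem
        order.append(name)

    chi_names = table.chi_names(name3)
    chi_vals = []
    for cn, ideal in zip(chi_names, entry["chi_ideal"]):
        if cn in pred.torsions:
            chi_vals.append(float(pred.torsions[cn]))
        else:
            warnings.warn(
                f"{name3}: torsion {cn} not supplied, using canonical "
                f"value {ideal:.1f} deg",
                stacklevel=2,
            )
            chi_vals.append(ideal)

    for rec in entry["atoms"]:
        t, g, p = (pos[r] for r in rec["refs"])
        if "chi" in rec:
            tors = chi_vals[rec["chi"]] + rec["offset"]
        else:
            tors = rec["torsion"]
        pos[rec["name"]] = place_atom(t, g, p, rec["bond"], rec["angle"],
                                      tors)
        elements[rec["name"]] = rec["element"]
        order.append(rec["name"])

    lead = [n for n in _BACKBONE_FIRST[pred.polymer_class] if n in pos]
    ordered = lead + [n for n in order if n not in lead]
    b = pred.confidence
    atoms = [Atom(n, elements[n], pos[n], b_factor=b) for n in ordered]
    return Residue(seq_id=seq_id, identity=identity, atoms=atoms)


def measure_torsions(residue: Residue, polymer: str = "amino") -> dict:
    """Measure the rotatable torsions (degrees) of a built residue."""
    table = geometry_table()
    name3 = alphabets.residue_name(residue.identity, polymer)
    entry = table.entry(name3)
    out = {}
    for cn, quad in zip(table.chi_names(name3), entry["chi_atoms"]):
        out[cn] = dihedral(*(residue.atom(a).coord for a in quad))
    return out


# ---------------------------------------------------------------------------
# Coordinate file I/O (PDB / mmCIF via gemmi)

_AMINO3 = set(alphabets.AMINO_THREE.values())
_NUC = set(alphabets.NUCLEOTIDE_LETTERS)


def _detect_format(path, format):
    if format is not None:
        return format
    s = str(path).lower()
    if s.endswith((".cif", ".mmcif")):
        return "mmcif"
    if s.endswith((".pdb", ".ent")):
        return "pdb"
    raise ValueError(f"cannot infer coordinate format from {path!r}")


def write_model(model: AtomicModel, path, format: str | None = None) -> None:
    """Write a model as PDB or mmCIF. Confidence scores go to the B-factor
    column (two decimals in PDB)."""
    fmt = _detect_format(path, format)
    st = gemmi.Structure()
    st.name = Path(path).stem
    md = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = alphabets.residue_name(res.identity, chain.polymer)
            gr.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.b_iso = atom.b_factor
                ga.occ = atom.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        md.add_chain(gc)
    st.add_model(md)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def read_model(path, format: str | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file. Files with insertion codes are rejected."""
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    else:
        st = gemmi.read_structure(str(path),
                                  format=gemmi.CoorFormat.Mmcif)
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    md = st[0]
    chains = []
    for gc in md:
        residues = []
        n_amino = n_nuc = 0
        for gr in gc:
            if gr.seqid.icode not in ("", " "):
                raise ValueError(
                    f"{path}: insertion code {gr.seqid.icode!r} at "
                    f"{gc.name}/{gr.seqid.num} — models with insertion "
                    "codes are not supported"
                )
            if gr.name in _AMINO3 or gr.name == "UNK":
                n_amino += 1
            elif gr.name in _NUC:
                n_nuc += 1
            atoms = [
                Atom(a.name, a.element.name, np.array(
                    [a.pos.x, a.pos.y, a.pos.z]), a.b_iso, a.occ)
                for a in gr
            ]
            residues.append(
                Residue(gr.seqid.num, "?", atoms)  # identity fixed below
            )
        polymer = "nucleotide" if n_nuc > n_amino else "amino"
        for gr, res in zip(gc, residues):
            res.identity = alphabets.one_letter(gr.name, polymer)
        chains.append(Chain(gc.name, polymer, residues))
    return AtomicModel(chains)


# ---------------------------------------------------------------------------
# Prediction interchange format (JSON)

def write_predictions(preds: list[ResiduePrediction], path) -> None:
    """Write predicted residues to the JSON interchange format: one record
    per residue with position, frame (9 floats, row-major), identity
    probabilities, confidence, predicted r.m.s.d. and torsions."""
    records = [
        {
            "position": p.position.tolist(),
            "frame": p.frame.reshape(9).tolist(),
            "identity_probs": p.identity_probs.tolist(),
            "confidence": p.confidence,
            "predicted_rmsd": p.predicted_rmsd,
            "torsions": p.torsions,
            "polymer_class": p.polymer_class,
        }
        for p in preds
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_predictions(path) -> list[ResiduePrediction]:
    records = json.loads(Path(path).read_text())
    return [
        ResiduePrediction(
            position=np.array(r["position"]),
            frame=np.array(r["frame"]).reshape(3, 3),
            identity_probs=np.array(r["identity_probs"]),
            confidence=r["confidence"],
            predicted_rmsd=r.get("predicted_rmsd", 0.0),
            torsions=r.get("torsions", {}),
            polymer_class=r.get("polymer_class", "amino"),
        )
        for r in records
    ]
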