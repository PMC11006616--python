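"""Model evaluation metrics: Q-score, backbone r.m.s.d., completeness and
model-to-map Fourier shell correlation.

All comparisons assume the predicted and reference models share the map's
coordinate frame: no superposition is performed anywhere. Residue
correspondence is established by greedy nearest-first one-to-one matching
of anchor atoms (Cα for protein, P for nucleic acids) within a match
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .density import DensityMap, interpolate
from .model import AtomicModel

__all__ = ["QScoreResult", "qscore", "RmsdResult", "backbone_rmsd",
           "CompletenessResult", "completeness", "FSCCurve",
           "model_map_fsc", "simulate_density"]

BACKBONE_ATOMS = {
    "amino": ("N", "CA", "C", "O"),
    "nucleotide": ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
}

# approximate atomic numbers for the elements seen in protein/NA models
_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


# ---------------------------------------------------------------------------
# Q-score

def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci sphere); fixed, not random."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z ** 2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass
class QScoreResult:
    """Per-atom and aggregated atom-resolvability scores."""

    per_atom: list  # (chain_id, seq_id, atom_name, q, flag)
    per_residue: dict  # (chain_id, seq_id) -> mean Q
    model_mean: float

    def atom_scores(self) -> np.ndarray:
        return np.array([rec[3] for rec in self.per_atom])


def qscore(model: AtomicModel, dmap: DensityMap, sigma: float = 0.6,
           max_radius: float = 2.0, shell_step: float = 0.1,
           points_per_shell: int = 24) -> QScoreResult:
    """Q-score: how well the map resolves each atom.

    For every atom the map is sampled on radial shells (``shell_step``
    spacing out to ``max_radius``, fixed quasi-uniform directions per
    shell); sample points closer to a different atom are excluded. Q is
    the normalized cross-correlation (about the mean) between the sampled
    values and a reference Gaussian ``exp(-0.5 (r/sigma)^2)``, so it is
    invariant to affine rescaling of the map and lies in [-1, 1]. Atoms in
    flat (zero-variance) density get Q = 0 with a ``zero-variance`` flag;
    atoms outside the map are excluded with an ``outside-map`` flag.
    """
    atoms = [(c.chain_id, r.seq_id, a.name, a.coord)
             for c, r in model.all_residues() for a in r.atoms]
    if not atoms or dmap.grid.size == 0:
        raise ValueError("empty model or map")
    coords = np.array([a[3] for a in atoms])
    tree = cKDTree(coords)

    radii = np.arange(shell_step, max_radius + 1e-9, shell_step)
    dirs = _fibonacci_directions(points_per_shell)
    offsets = np.concatenate(
        [np.zeros((1, 3))] + [r * dirs for r in radii])  # (P, 3)
    ref = np.concatenate(
        [[1.0]] + [np.full(points_per_shell, np.exp(-0.5 * (r / sigma) ** 2))
                   for r in radii])  # (P,)
    P = len(offsets)

    lo, hi = dmap.origin, dmap.origin + dmap.extent
    per_atom = []
    residue_acc: dict = {}
    for ai, (cid, rid, aname, c) in enumerate(atoms):
        if np.any(c < lo) or np.any(c > hi):
            per_atom.append((cid, rid, aname, np.nan, "outside-map"))
            continue
        pts = c + offsets
        _, nearest = tree.query(pts, k=1)
        mask = nearest == ai
        if mask.sum() < 4:
            per_atom.append((cid, rid, aname, 0.0, "too-few-points"))
            residue_acc.setdefault((cid, rid), []).append(0.0)
            continue
        vals = interpolate(dmap, pts[mask])
        g = ref[mask]
        v = vals - vals.mean()
        u = g - g.mean()
        denom = np.linalg.norm(v) * np.linalg.norm(u)
        if denom < 1e-12:
            per_atom.append((cid, rid, aname, 0.0, "zero-variance"))
            residue_acc.setdefault((cid, rid), []).append(0.0)
            continue
        q = float(np.dot(v, u) / denom)
        per_atom.append((cid, rid, aname, q, ""))
        residue_acc.setdefault((cid, rid), []).append(q)

    per_residue = {k: float(np.mean(v)) for k, v in residue_acc.items()}
    all_q = [rec[3] for rec in per_atom if rec[4] != "outside-map"]
    model_mean = float(np.mean(all_q)) if all_q else 0.0
    return QScoreResult(per_atom, per_residue, model_mean)


# ---------------------------------------------------------------------------
# residue matching, r.m.s.d. and completeness

def greedy_match(ref_pts: np.ndarray, pred_pts: np.ndarray,
                 radius: float) -> list:
    """One-to-one nearest-first matching of reference to predicted points
    within ``radius``. Candidate pairs are taken shortest-distance first
    (ties broken by reference then predicted index); each point is used at
    most once. Returns (ref_index, pred_index, distance) triples."""
    if len(ref_pts) == 0 or len(pred_pts) == 0:
        return []
    tree = cKDTree(pred_pts)
    cand = []
    for i, neighbors in enumerate(tree.query_ball_point(ref_pts, radius)):
        for j in neighbors:
            cand.append((float(np.linalg.norm(ref_pts[i] - pred_pts[j])),
                         i, j))
    cand.sort()
    used_r: set = set()
    used_p: set = set()
    out = []
    for d, i, j in cand:
        if i in used_r or j in used_p:
            continue
        used_r.add(i)
        used_p.add(j)
        out.append((i, j, d))
    out.sort()
    return sorted(out)


def _flat_residues(model: AtomicModel):
    return [(c, r) for c, r in model.all_residues()]


@dataclass
class RmsdResult:
    per_residue: list  # (chain_id, seq_id, rmsd)
    global_rmsd: float
    n_matched: int


def backbone_rmsd(pred: AtomicModel, ref: AtomicModel,
                  match_radius: float = 3.0) -> RmsdResult:
    """Backbone r.m.s.d. between matched residues, in the shared map frame.

    Reference residues are matched one-to-one to the nearest predicted
    anchor within ``match_radius`` (greedy nearest-first); the r.m.s.d.
    runs over the backbone atoms present in both partners. The global
    value is the root of the mean squared deviation over all matched
    backbone atoms. Zero matches yield an empty result.
    """
    if pred.n_residues == 0 or ref.n_residues == 0:
        raise ValueError("both models must be non-empty")
    rres = _flat_residues(ref)
    pres = _flat_residues(pred)
    matches = greedy_match(
        np.array([r.anchor for _, r in rres]),
        np.array([r.anchor for _, r in pres]), match_radius)
    per_residue = []
    sq_sum, n_atoms = 0.0, 0
    for i, j, _ in matches:
        rc, rr = rres[i]
        _, pr = pres[j]
        names = [n for n in BACKBONE_ATOMS[rc.polymer]
                 if rr.has_atom(n) and pr.has_atom(n)]
        if not names:
            continue
        devs = [rr.atom(n).coord - pr.atom(n).coord for n in names]
        sq = np.sum(np.square(devs))
        per_residue.append(
            (rc.chain_id, rr.seq_id, float(np.sqrt(sq / len(names)))))
        sq_sum += sq
        n_atoms += len(names)
    glob = float(np.sqrt(sq_sum / n_atoms)) if n_atoms else float("nan")
    return RmsdResult(per_residue, glob, len(per_residue))


@dataclass
class CompletenessResult:
    matched: int
    reference_total: int
    fraction: float
    records: list  # (chain_id, seq_id, distance|None, identity_ok|None)

    def __post_init__(self):
        assert 0 <= self.fraction <= 1


def completeness(pred: AtomicModel, ref: AtomicModel, cutoff: float = 3.0,
                 require_identity: bool = True) -> CompletenessResult:
    """Fraction of reference residues built by the predicted model.

    A reference residue counts as built when a one-to-one matched
    predicted anchor (Cα / P) lies within ``cutoff`` (default 3 Å) and —
    with ``require_identity`` — the residue identity agrees. With
    ``require_identity=False`` this is backbone completeness; with it,
    sequence completeness.
    """
    rres = _flat_residues(ref)
    pres = _flat_residues(pred)
    matches = {i: (j, d) for i, j, d in greedy_match(
        np.array([r.anchor for _, r in rres]) if rres else np.zeros((0, 3)),
        np.array([r.anchor for _, r in pres]) if pres else np.zeros((0, 3)),
        cutoff)}
    records = []
    n_ok = 0
    for i, (rc, rr) in enumerate(rres):
        if i not in matches:
            records.append((rc.chain_id, rr.seq_id, None, None))
            continue
        j, d = matches[i]
        id_ok = pres[j][1].identity == rr.identity
        ok = id_ok or not require_identity
        n_ok += ok
        records.append((rc.chain_id, rr.seq_id, d, id_ok))
    total = len(rres)
    frac = n_ok / total if total else 0.0
    return CompletenessResult(n_ok, total, frac, records)


# ---------------------------------------------------------------------------
# model-to-map FSC

def simulate_density(model: AtomicModel, template: DensityMap | None = None,
                     voxel: float = 1.0, sigma: float | None = None,
                     atom_b: float = 30.0, pad: float = 5.0,
                     weight_scale: float = 1.0) -> DensityMap:
    """Render a model as a sum of per-atom Gaussians.

    With ``template`` given, density is synthesized on that map's exact
    grid (no resampling of experimental data); otherwise a new grid with
    ``pad`` Å margins is created. Gaussian width comes from ``sigma``
    directly or from the B-factor ``atom_b`` via sigma^2 = B / (8 pi^2);
    atoms are weighted by atomic number times ``weight_scale``.
    """
    atoms = [(a.element, a.coord) for _, r in model.all_residues()
             for a in r.atoms]
    if not atoms:
        raise ValueError("empty model")
    coords = np.array([c for _, c in atoms])
    weights = np.array([_ATOMIC_NUMBER.get(e, 6) for e, _ in atoms],
                       dtype=float) * weight_scale
    if sigma is None:
        sigma = float(np.sqrt(atom_b / (8 * np.pi ** 2)))
    if template is not None:
        shape = template.grid.shape
        origin = template.origin.copy()
        voxel_size = template.voxel_size.copy()
    else:
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        voxel_size = np.full(3, float(voxel))
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel)) + 1
                      for a in range(3))
        origin = lo
    grid = np.zeros(shape, dtype=np.float64)
    cut = 4.0 * sigma
    rng_idx = [np.arange(n) for n in shape]
    for w, c in zip(weights, coords):
        idx = (c - origin) / voxel_size
        lo_i = np.maximum(np.ceil(idx - cut / voxel_size), 0).astype(int)
        hi_i = np.minimum(np.floor(idx + cut / voxel_size),
                          np.array(shape) - 1).astype(int)
        if np.any(lo_i > hi_i):
            continue
        ax = [rng_idx[a][lo_i[a]:hi_i[a] + 1] * voxel_size[a]
              + origin[a] - c[a] for a in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        grid[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1,
             lo_i[2]:hi_i[2] + 1] += w * np.exp(-0.5 * r2 / sigma ** 2)
    return DensityMap(grid.astype(np.float32), voxel_size, origin)


@dataclass
class FSCCurve:
    frequencies: np.ndarray  # shell centers, 1/Å
    correlation: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        self.correlation = np.asarray(self.correlation, float)

    def to_tsv(self) -> str:
        lines = ["frequency\tfsc"]
        for f, c in zip(self.frequencies, self.correlation):
            lines.append(f"{f:.6f}\t{c:.6f}")
        return "\n".join(lines) + "\n"


def fsc_between(a: np.ndarray, b: np.ndarray, voxel: float) -> FSCCurve:
    """Fourier shell correlation between two equally shaped volumes."""
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    n = max(a.shape)
    pad = [(0, n - s) for s in a.shape]  # pad to cubic
    fa = np.fft.fftn(np.pad(a, pad))
    fb = np.fft.fftn(np.pad(b, pad))
    freq = np.fft.fftfreq(n, d=voxel)
    kx, ky, kz = np.meshgrid(freq, freq, freq, indexing="ij")
    kr = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    dk = 1.0 / (n * voxel)
    shells = np.minimum((kr / dk + 0.5).astype(int), n)  # bin index
    n_shells = n // 2 + 1
    num = np.zeros(n_shells)
    da = np.zeros(n_shells)
    db = np.zeros(n_shells)
    flat = shells.ravel()
    valid = flat < n_shells
    np.add.at(num, flat[valid], np.real(fa * np.conj(fb)).ravel()[valid])
    np.add.at(da, flat[valid], np.abs(fa).ravel()[valid] ** 2)
    np.add.at(db, flat[valid], np.abs(fb).ravel()[valid] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(da * db)
    corr = np.nan_to_num(corr, nan=0.0)
    return FSCCurve(np.arange(n_shells) * dk, corr)


def model_map_fsc(model: AtomicModel, dmap: DensityMap,
                  atom_b: float = 30.0) -> FSCCurve:
    """Model-to-map FSC: simulate density from the model on the map's own
    grid and correlate the two volumes per spherical frequency shell."""
    sim = simulate_density(model, template=dmap, atom_b=atom_b)
    voxel = float(dmap.voxel_size[0])
    if not np.allclose(dmap.voxel_size, voxel):
        raise ValueError("anisotropic voxels are not supported for FSC")
    return fsc_between(dmap.grid.astype(float), sim.grid.astype(float),
                       voxel)
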