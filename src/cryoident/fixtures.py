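"""Synthetic inputs for exercising the pipeline without external data.

The emulator stands in for the upstream neural predictor: given a true
sequence and backbone trace, it draws identity-probability vectors from a
Dirichlet centred on the truth, perturbs positions with isotropic Gaussian
noise, and ties each residue's confidence to whether its sampled argmax is
correct. Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import alphabets
from .model import AtomicModel, ResiduePrediction
from .metrics import simulate_density
from .density import DensityMap

__all__ = ["EmulatorConfig", "emulate_predictions", "make_helix_trace",
           "simulate_map", "make_decoy_db", "write_fasta", "read_fasta"]


@dataclass
class EmulatorConfig:
    """Controls how faithful the emulated predictions are.

    ``accuracy`` is the expected probability mass on the true identity
    (1.0 gives exact one-hot vectors); ``concentration`` the Dirichlet
    concentration (sharper but noisier at the default 50);
    ``position_noise`` the isotropic Gaussian sigma added to coordinates
    in Å. Confidence is ``confidence_correct`` when the sampled argmax
    equals the truth and ``confidence_wrong`` otherwise, plus uniform
    jitter of half-width ``confidence_jitter``, clamped to [0, 1]."""

    accuracy: float = 0.8
    concentration: float = 50.0
    position_noise: float = 0.0
    seed: int = 0
    confidence_correct: float = 0.9
    confidence_wrong: float = 0.4
    confidence_jitter: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.position_noise < 0:
            raise ValueError("position_noise must be non-negative")


def emulate_predictions(sequence: str, coords: np.ndarray,
                        cfg: EmulatorConfig,
                        polymer: str = "amino"
                        ) -> list[ResiduePrediction]:
    """Emulate per-residue predictions for a known sequence and trace."""
    letters = alphabets.letters(polymer)
    K = len(letters)
    coords = np.asarray(coords, dtype=float)
    if len(sequence) != len(coords):
        raise ValueError("sequence and coordinate trace lengths differ")
    bad = [ch for ch in sequence if ch not in letters]
    if bad:
        raise ValueError(f"sequence letters {sorted(set(bad))} not in the "
                         f"{polymer} alphabet")
    rng = np.random.default_rng(cfg.seed)
    preds = []
    a = cfg.accuracy
    for ch, xyz in zip(sequence, coords):
        true_idx = letters.index(ch)
        mean = np.full(K, (1.0 - a) / (K - 1))
        mean[true_idx] = a
        if a >= 1.0:
            probs = np.zeros(K)
            probs[true_idx] = 1.0
        else:
            probs = rng.dirichlet(np.maximum(cfg.concentration * mean,
                                             1e-8))
            probs /= probs.sum()
        pos = xyz + rng.normal(0.0, cfg.position_noise, size=3)
        frame = Rotation.random(random_state=rng).as_matrix()
        correct = int(np.argmax(probs)) == true_idx
        c0 = cfg.confidence_correct if correct else cfg.confidence_wrong
        c = float(np.clip(
            c0 + rng.uniform(-cfg.confidence_jitter, cfg.confidence_jitter),
            0.0, 1.0))
        # invert the linear confidence map to a matching predicted r.m.s.d.
        rmsd = 1.2 - 0.7 * c
        preds.append(ResiduePrediction(
            position=pos, frame=frame, identity_probs=probs,
            confidence=c, predicted_rmsd=rmsd, polymer_class=polymer))
    return preds


def make_helix_trace(n: int, rise: float = 1.5, turn: float = 100.0,
                     radius: float = 2.28) -> np.ndarray:
    """Ideal alpha-helical Cα trace: ``n`` points with the given rise per
    residue (Å) and turn (degrees). The default radius makes consecutive
    Cα-Cα distances come out at ~3.8 Å."""
    if n < 1:
        raise ValueError("need at least one residue")
    i = np.arange(n)
    theta = np.radians(turn) * i
    pts = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                    rise * i], axis=1)
    return pts - pts[0]


def simulate_map(model: AtomicModel, voxel: float = 1.0,
                 sigma: float = 0.6, noise_rms: float = 0.0,
                 seed: int = 0, pad: float = 5.0,
                 weight_scale: float = 1.0) -> DensityMap:
    """Simulated map: per-atom Gaussians of width ``sigma`` on a grid
    padded ``pad`` Å beyond the model, plus seeded Gaussian noise of the
    given RMS. Linear in the atom weights."""
    dmap = simulate_density(model, voxel=voxel, sigma=sigma, pad=pad,
                            weight_scale=weight_scale)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        dmap.grid = (dmap.grid
                     + rng.normal(0.0, noise_rms, dmap.grid.shape)
                     ).astype(np.float32)
    return dmap


def make_decoy_db(n: int, length_range: tuple = (50, 400),
                  polymer: str = "amino", seed: int = 0,
                  plant: tuple | None = None,
                  background: np.ndarray | None = None) -> list:
    """Decoy sequence database: ``n`` i.i.d. sequences drawn from the
    background composition (uniform by default), plus an optional planted
    true sequence as ``(id, sequence)``. Returns (id, sequence) pairs,
    deterministic under the seed."""
    if n < 1:
        raise ValueError("need at least one decoy")
    letters = list(alphabets.letters(polymer))
    if background is None:
        background = np.full(len(letters), 1.0 / len(letters))
    background = np.asarray(background, float)
    background = background / background.sum()
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    width = max(len(str(n)), 4)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=background))
        records.append((f"decoy_{i:0{width}d}", seq))
    if plant is not None:
        records.append((plant[0], str(plant[1])))
    return records


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA (byte-deterministic)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> list:
    """Read FASTA into (id, sequence) pairs."""
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path),
                                                          "fasta")]
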