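import warnings

import numpy as np
import pytest

from cryoident import AtomicModel, Chain, Residue, Atom
from cryoident.fixtures import (EmulatorConfig, emulate_predictions,
                                make_helix_trace)
from cryoident.model import build_full_atoms


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def helix_predictions(sequence, accuracy=1.0, seed=0, position_noise=0.0):
    """Emulated predictions for a sequence laid on an ideal helix trace."""
    trace = make_helix_trace(len(sequence))
    cfg = EmulatorConfig(accuracy=accuracy, seed=seed,
                         position_noise=position_noise)
    return emulate_predictions(sequence, trace, cfg)


def ca_trace_model(n=30, chain_id="A", identity_cycle="ACDEFGHIKL",
                   offset=(0.0, 0.0, 0.0)):
    """A Cα-only helical model with cyclic identities."""
    trace = make_helix_trace(n) + np.asarray(offset)
    residues = [
        Residue(i + 1, identity_cycle[i % len(identity_cycle)],
                [Atom("CA", "C", trace[i])])
        for i in range(n)
    ]
    return AtomicModel([Chain(chain_id, "amino", residues)])


def full_atom_model(sequence, seed=0):
    """Full-atom helical model built from noiseless emulated predictions."""
    preds = helix_predictions(sequence, accuracy=1.0, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # canonical-rotamer fallbacks
        residues = [build_full_atoms(p, s, i + 1)
                    for i, (p, s) in enumerate(zip(preds, sequence))]
    return AtomicModel([Chain("A", "amino", residues)])
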