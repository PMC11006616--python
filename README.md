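# cryoident

Deterministic machinery for automated model building in cryo-EM maps:
converting per-residue identity predictions into profile HMMs for protein
identification, post-processing predicted residues into complete atomic
models, and evaluating those models against maps.

Modern model-building networks predict, for every residue they detect in a
density map, a position, an orientation frame, a probability vector over
the 20 amino acids (or 4 nucleotides), and a confidence score. This package
implements everything downstream of those predictions:

- **Profile-HMM identification.** Each traced chain becomes a profile HMM
  whose match emissions are the predicted identity probabilities and whose
  transition probabilities derive from the per-residue confidence *c* via

  ```
  P(M→M) = max(c − d, 0.5)        P(D→M) = P(I→M) = 1 − d
  P(M→D) = P(M→I) = (1 − P(M→M))/2
  P(D→D) = P(I→I) = d             P(I→D) = P(D→I) = 0
  ```

  with *d* = 0.5. Profiles serialize to HMMER3/f ASCII and can be searched
  with external HMMER or with the built-in Viterbi engine (local log-odds
  alignment in bits). Chains with known input sequences are *mutated* to
  their matched identities; unknown chains are searched against a whole
  proteome, with weak hits bootstrapped by cross-referencing multiple
  copies of the same protein.

- **Post-processing.** A k-nearest-neighbour graph (k = 20) over predicted
  positions is traced into chains, fragments on the same sequence are
  connected when their spatial gap is compatible with the number of
  missing residues, chains shorter than 4 residues are pruned, and full
  atomic models are generated from idealized internal-coordinate geometry
  plus the predicted torsion angles. The predicted backbone r.m.s.d. is
  mapped linearly to a confidence score between 0 and 1 over the range
  1.2 → 0.5 Å and stored in the B-factor column of the output coordinates.

- **Evaluation.** Q-scores (atom resolvability: correlation of radially
  sampled density against a reference Gaussian), backbone r.m.s.d. and
  model completeness (fraction of reference residues with a matched Cα
  within 3 Å and, optionally, the correct identity), and model-to-map
  Fourier shell correlation.

- **Synthetic fixtures.** A seeded emulator stands in for the upstream
  network so that every workflow — including proteome-wide identification
  against a 1,000-entry decoy database — runs from scratch in seconds.

## Worked example

Identify an unknown 80-residue chain against a 201-entry proteome, with
predictions emulated at accuracy 0.7:

```python
import numpy as np
from cryoident import alphabets
from cryoident.fixtures import (EmulatorConfig, emulate_predictions,
                                make_decoy_db, make_helix_trace)
from cryoident.hmm import build_profile, search_database

rng = np.random.default_rng(7)
seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 80))
preds = emulate_predictions(seq, make_helix_trace(80),
                            EmulatorConfig(accuracy=0.7, seed=7))
proteome = make_decoy_db(200, length_range=(50, 300), seed=8,
                         plant=("true_protein", seq))
for rank, h in enumerate(search_database(build_profile(preds, name="chain_A"),
                                         proteome, top_n=3), 1):
    print(f"{rank}  {h.target_id:>13}  {h.bit_score:8.1f} bits  "
          f"coverage {h.coverage:.2f}")
```

prints

```
1   true_protein     218.6 bits  coverage 1.00
2     decoy_0103       9.6 bits  coverage 0.07
3     decoy_0118       9.4 bits  coverage 0.07
```

— the planted source protein wins by more than 200 bits over the best
decoy, even though only ~70% of the probability mass sits on the true
residue at each position. The same run through
`identify_unknown({"A": preds}, proteome)` reports
`true_protein: chains A (combined 218.6 bits)`.

A CLI mirrors the main workflows:

```
cryoident simulate --seed 7 --out fixtures/
cryoident search --hmm fixtures/chain.hmm --db fixtures/proteome.fasta --out hits.tsv
cryoident map resample --in map.mrc --voxel 1.0 --out out.mrc
cryoident evaluate --pred model.cif --ref deposited.cif --map map.mrc --out metrics/
```

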