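"""Profile HMMs built from per-residue identity probabilities.

Instead of estimating a profile HMM from a multiple-sequence alignment, the
profile here is constructed directly from per-residue predictions: match
emissions are the predicted identity-probability vectors, and transition
probabilities are derived from each residue's confidence c through

    P(M->M) = max(c - d, 0.5)      P(D->M) = P(I->M) = 1 - d
    P(M->D) = P(M->I) = (1 - P(M->M)) / 2
    P(D->D) = P(I->I) = d          P(I->D) = P(D->I) = 0

with the constant d = 0.5 by default. Profiles serialize to the HMMER3/f
ASCII format and can be searched against sequence databases either with
external HMMER or with the internal Viterbi engine implemented here (local
log-odds alignment in bits; E-value calibration is left to HMMER).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import alphabets

__all__ = [
    "TransitionRow", "ProfileHMM", "SearchHit", "DEFAULT_D",
    "transitions_from_confidence", "build_profile",
    "write_hmmer3", "parse_hmmer3", "HmmFormatError",
    "viterbi_search", "search_database",
]

DEFAULT_D = 0.5

# Uniform-entry local alignment: a path may start at any of the L match
# states, costing log2(1/L) bits; exit from any match state is free.
NO_HIT_SCORE = -np.inf


@dataclass(frozen=True)
class TransitionRow:
    """Transition probabilities out of one profile position (node i to
    node i+1). I->D and D->I are structurally zero."""

    p_mm: float
    p_mi: float
    p_md: float
    p_im: float
    p_ii: float
    p_dm: float
    p_dd: float
    p_id: float = 0.0
    p_di: float = 0.0

    def __post_init__(self):
        for triplet, names in (
            ((self.p_mm, self.p_mi, self.p_md), "M->{M,I,D}"),
            ((self.p_im, self.p_ii, self.p_id), "I->{M,I,D}"),
            ((self.p_dm, self.p_dd, self.p_di), "D->{M,D,I}"),
        ):
            if any(p < 0 or p > 1 for p in triplet):
                raise ValueError(f"{names} probabilities outside [0, 1]")
            if abs(sum(triplet) - 1.0) > 1e-9:
                raise ValueError(
                    f"{names} must sum to 1, got {sum(triplet)!r}")
        if self.p_id != 0.0 or self.p_di != 0.0:
            raise ValueError("I->D and D->I transitions must be zero")

    def as_array(self) -> np.ndarray:
        """The 7 free transitions in HMMER order:
        m->m, m->i, m->d, i->m, i->i, d->m, d->d."""
        return np.array([self.p_mm, self.p_mi, self.p_md, self.p_im,
                         self.p_ii, self.p_dm, self.p_dd])


def transitions_from_confidence(c: float, d: float = DEFAULT_D
                                ) -> TransitionRow:
    """Build one transition row from a residue confidence c in [0, 1]."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"confidence c={c!r} outside [0, 1]")
    if not 0.0 <= d < 1.0:
        raise ValueError(f"constant d={d!r} outside [0, 1)")
    p_mm = max(c - d, 0.5)
    p_mi = p_md = (1.0 - p_mm) / 2.0
    return TransitionRow(p_mm=p_mm, p_mi=p_mi, p_md=p_md,
                         p_im=1.0 - d, p_ii=d,
                         p_dm=1.0 - d, p_dd=d)


def _terminal_row(row: TransitionRow) -> TransitionRow:
    """Fold the last node's delete branch into the exit: the final match
    state can only continue to the end state or open an insert, and a
    final delete state exits with certainty."""
    return TransitionRow(p_mm=row.p_mm + row.p_md, p_mi=row.p_mi, p_md=0.0,
                         p_im=row.p_im, p_ii=row.p_ii,
                         p_dm=1.0, p_dd=0.0)


@dataclass
class ProfileHMM:
    """A positional profile HMM over an amino or nucleotide alphabet."""

    name: str
    alphabet: str  # index order of emission columns
    match_emissions: np.ndarray  # (L, K)
    insert_emissions: np.ndarray  # (L, K)
    transitions: list  # L TransitionRow; row i governs node i -> i+1
    background: np.ndarray  # (K,)

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.insert_emissions = np.asarray(self.insert_emissions, float)
        self.background = np.asarray(self.background, float)
        L, K = self.match_emissions.shape
        if L < 1:
            raise ValueError("profile needs at least one match state")
        if K != len(self.alphabet):
            raise ValueError("emission width does not match alphabet")
        if self.insert_emissions.shape != (L, K):
            raise ValueError("insert_emissions shape mismatch")
        if len(self.transitions) != L:
            raise ValueError("need one transition row per match state")
        for m, lbl in ((self.match_emissions, "match"),
                       (self.insert_emissions, "insert"),
                       (self.background[None, :], "background")):
            if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-6):
                raise ValueError(f"{lbl} emission rows must be simplexes")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        return "".join(self.alphabet[i]
                       for i in np.argmax(self.match_emissions, axis=1))

    def reversed(self) -> "ProfileHMM":
        """The profile read back-to-front (for fragments whose chain
        direction is unknown)."""
        rows = list(reversed(self.transitions))
        rows[-1] = _terminal_row(rows[-1])
        return ProfileHMM(
            name=self.name + "|rev", alphabet=self.alphabet,
            match_emissions=self.match_emissions[::-1].copy(),
            insert_emissions=self.insert_emissions[::-1].copy(),
            transitions=rows,
            background=self.background.copy(),
        )


def build_profile(preds, d: float = DEFAULT_D,
                  background: np.ndarray | None = None,
                  name: str = "chain") -> ProfileHMM:
    """Build a profile HMM from one chain of residue predictions.

    Match emissions are the predicted identity probabilities, insert
    emissions the background (uniform unless given), and transitions come
    from each residue's confidence via
    :func:`transitions_from_confidence`. The final node's delete branch is
    folded into the exit so the serialized profile is well formed.
    """
    preds = list(preds)
    if not preds:
        raise ValueError("cannot build a profile from an empty chain")
    polymer = preds[0].polymer_class
    if any(p.polymer_class != polymer for p in preds):
        raise ValueError("mixed polymer classes in one chain")
    alphabet = alphabets.letters(polymer)
    K = len(alphabet)
    if background is None:
        background = np.full(K, 1.0 / K)
    background = np.asarray(background, float)
    match = np.stack([p.identity_probs for p in preds])
    insert = np.tile(background, (len(preds), 1))
    rows = [transitions_from_confidence(p.confidence, d) for p in preds]
    rows[-1] = _terminal_row(rows[-1])
    return ProfileHMM(name=name, alphabet=alphabet, match_emissions=match,
                      insert_emissions=insert, transitions=rows,
                      background=background)


# ---------------------------------------------------------------------------
# HMMER3/f ASCII serialization

class HmmFormatError(ValueError):
    """Raised when an HMMER3 file cannot be parsed."""


_ALPH_NAME = {alphabets.AMINO_LETTERS: "amino",
              alphabets.NUCLEOTIDE_LETTERS: "RNA"}
_ALPH_FROM_NAME = {"amino": alphabets.AMINO_LETTERS,
                   "rna": alphabets.NUCLEOTIDE_LETTERS,
                   "dna": alphabets.NUCLEOTIDE_LETTERS}


def _fmt(p: float) -> str:
    """Probability as negative natural log, '*' for zero."""
    if p <= 0.0:
        return "      *"
    return f"{max(-math.log(p), 0.0):.5f}"


def _parse_val(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_hmmer3(profile: ProfileHMM, path) -> None:
    """Write a profile in the HMMER3/f ASCII dialect."""
    K = len(profile.alphabet)
    lines = []
    lines.append("HMMER3/f [3.1b2 | cryoident profile]")
    lines.append(f"NAME  {profile.name}")
    lines.append(f"LENG  {profile.length}")
    lines.append(f"ALPH  {_ALPH_NAME[profile.alphabet]}")
    lines.append("RF    no")
    lines.append("MM    no")
    lines.append("CONS  yes")
    lines.append("CS    no")
    lines.append("MAP   yes")
    # Uncalibrated Gumbel placeholders (lambda = ln 2): HMMER versions
    # refuse to report hits from profiles without STATS lines. Bit scores
    # are unaffected; E-values from these parameters are not calibrated.
    lines.append("STATS LOCAL MSV       -9.0000  0.69315")
    lines.append("STATS LOCAL VITERBI   -9.9000  0.69315")
    lines.append("STATS LOCAL FORWARD   -6.3000  0.69315")
    head = "  ".join(f"{a:>7}" for a in profile.alphabet)
    lines.append(f"HMM      {head}")
    lines.append("        " + "  ".join(
        f"{t:>7}" for t in
        ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")))
    # averaged match emissions, as hmmbuild's COMPO line
    compo = profile.match_emissions.mean(axis=0)
    lines.append("  COMPO   " + "  ".join(_fmt(p) for p in compo))
    # node 0: begin/insert-0 state; insert emissions = background
    lines.append("          " + "  ".join(_fmt(p)
                                          for p in profile.background))
    first = profile.transitions[0]
    lines.append("          " + "  ".join(
        [_fmt(1.0), _fmt(0.0), _fmt(0.0),
         _fmt(first.p_im), _fmt(first.p_ii), _fmt(1.0), _fmt(0.0)]))
    cons = profile.consensus()
    for i in range(profile.length):
        em = "  ".join(_fmt(p) for p in profile.match_emissions[i])
        lines.append(f"{i + 1:>7} {em}{i + 1:>7} {cons[i]} - - -")
        lines.append("          " + "  ".join(
            _fmt(p) for p in profile.insert_emissions[i]))
        lines.append("          " + "  ".join(
            _fmt(p) for p in profile.transitions[i].as_array()))
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_hmmer3(path) -> ProfileHMM:
    """Parse an HMMER3/f ASCII file back into a :class:`ProfileHMM`."""
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    def err(lineno, msg):
        raise HmmFormatError(f"{path}:{lineno}: {msg}")

    lineno, line = next(it, (0, ""))
    if not line.startswith("HMMER3/f"):
        err(lineno, f"not an HMMER3/f file (got {line[:20]!r})")
    name = None
    length = None
    alphabet = None
    for lineno, line in it:
        key = line[:5].strip()
        val = line[5:].strip()
        if key == "NAME":
            name = val
        elif key == "LENG":
            try:
                length = int(val)
            except ValueError:
                err(lineno, f"bad LENG value {val!r}")
        elif key == "ALPH":
            alphabet = _ALPH_FROM_NAME.get(val.lower())
            if alphabet is None:
                err(lineno, f"unsupported alphabet {val!r}")
        elif line.startswith("HMM "):
            break
    else:
        err(lineno, "missing HMM emission header")
    if name is None or length is None or alphabet is None:
        err(lineno, "missing NAME, LENG or ALPH header line")
    K = len(alphabet)
    lineno, _ = next(it, (lineno, ""))  # transition-order header

    background = None
    match = np.zeros((length, K))
    insert = np.zeros((length, K))
    rows: list[TransitionRow] = []
    node = 0
    for lineno, line in it:
        toks = line.split()
        if not toks:
            continue
        if toks[0] == "//":
            break
        if toks[0] == "COMPO":
            continue
        if background is None:
            # node 0: insert emissions then its transition line
            if len(toks) != K:
                err(lineno, f"expected {K} node-0 insert emissions")
            background = np.array([_parse_val(t) for t in toks])
            lineno, line = next(it, (lineno, ""))
            if len(line.split()) != 7:
                err(lineno, "expected 7 node-0 transitions")
            continue
        if toks[0] != str(node + 1):
            err(lineno, f"expected node {node + 1}, got {toks[0]!r}")
        if len(toks) < 1 + K:
            err(lineno, f"expected {K} match emissions")
        match[node] = [_parse_val(t) for t in toks[1:1 + K]]
        lineno, line = next(it, (lineno, ""))
        toks = line.split()
        if len(toks) != K:
            err(lineno, f"expected {K} insert emissions")
        insert[node] = [_parse_val(t) for t in toks]
        lineno, line = next(it, (lineno, ""))
        toks = line.split()
        if len(toks) != 7:
            err(lineno, "expected 7 transition values")
        v = [_parse_val(t) for t in toks]
        # renormalize printed-precision rounding so row invariants hold
        mm, mi, md = v[0], v[1], v[2]
        sm = mm + mi + md
        im, ii = v[3], v[4]
        si = im + ii
        dm, dd = v[5], v[6]
        sd = dm + dd
        rows.append(TransitionRow(
            p_mm=mm / sm, p_mi=mi / sm, p_md=md / sm,
            p_im=im / si, p_ii=ii / si,
            p_dm=dm / sd, p_dd=dd / sd))
        node += 1
    if node != length:
        raise HmmFormatError(
            f"{path}: expected {length} nodes, found {node}")
    return ProfileHMM(name=name, alphabet=alphabet,
                      match_emissions=match / match.sum(1, keepdims=True),
                      insert_emissions=insert / insert.sum(1, keepdims=True),
                      transitions=rows,
                      background=background / background.sum())


# ---------------------------------------------------------------------------
# Viterbi local search

@dataclass
class SearchHit:
    """One profile-vs-sequence alignment."""

    target_id: str
    bit_score: float
    alignment: list = field(default_factory=list)  # (profile_pos, seq_pos, state)
    coverage: float = 0.0

    def __post_init__(self):
        m = [(p, s) for p, s, st in self.alignment if st == "M"]
        if any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("match positions must be strictly increasing")


def _encode(sequence: str, alphabet: str) -> np.ndarray:
    """Map residues to emission columns; anything outside the alphabet
    (ambiguity codes) maps to a sentinel column scored at background."""
    lut = {ch: i for i, ch in enumerate(alphabet)}
    return np.array([lut.get(ch, len(alphabet))
                     for ch in sequence.upper()], dtype=int)


def _score_tables(profile: ProfileHMM):
    """Per-state log2 tables. Match emission scores get an extra
    background-scored column for ambiguity codes; insert states score 0
    when insert emissions equal background."""
    with np.errstate(divide="ignore"):
        em = np.log2(profile.match_emissions / profile.background)
        em = np.hstack([em, np.zeros((profile.length, 1))])
        ins = np.log2(profile.insert_emissions / profile.background)
        ins = np.hstack([ins, np.zeros((profile.length, 1))])
        tr = np.log2(np.stack([t.as_array()
                               for t in profile.transitions]))
    return em, ins, tr


def viterbi_search(profile: ProfileHMM, sequence: str,
                   target_id: str = "seq") -> SearchHit:
    """Best local alignment of a sequence to the profile.

    Scoring is log-odds in bits: match states score
    ``log2(emission / background)``, transitions score ``log2 P``, entry
    into any match state costs ``log2(1/L)`` (uniform entry) and exit from
    any match state is free. Returns a hit with the Viterbi path; an empty
    sequence yields a no-hit sentinel with score ``-inf``.
    """
    x = _encode(sequence, profile.alphabet)
    n, L = len(x), profile.length
    if n == 0:
        return SearchHit(target_id, NO_HIT_SCORE, [], 0.0)
    em, ins, tr = _score_tables(profile)
    entry = -np.log2(L)
    NEG = -np.inf

    M = np.full((n, L), NEG)
    I = np.full((n, L), NEG)
    D = np.full((n, L), NEG)
    ptr = {}
    for j in range(n):
        for k in range(L):
            # match
            cands = [(entry, "S")]
            if j > 0 and k > 0:
                cands += [(M[j - 1, k - 1] + tr[k - 1, 0], "M"),
                          (I[j - 1, k - 1] + tr[k - 1, 3], "I"),
                          (D[j - 1, k - 1] + tr[k - 1, 5], "D")]
            best = max(cands, key=lambda t: t[0])
            M[j, k] = em[k, x[j]] + best[0]
            ptr[("M", j, k)] = best[1]
            # insert (after node k)
            if j > 0:
                a = M[j - 1, k] + tr[k, 1]
                b = I[j - 1, k] + tr[k, 4]
                I[j, k] = ins[k, x[j]] + max(a, b)
                ptr[("I", j, k)] = "M" if a >= b else "I"
            # delete
            if k > 0:
                a = M[j, k - 1] + tr[k - 1, 2]
                b = D[j, k - 1] + tr[k - 1, 6]
                D[j, k] = max(a, b)
                ptr[("D", j, k)] = "M" if a >= b else "D"

    j, k = np.unravel_index(np.argmax(M), M.shape)
    score = float(M[j, k])
    if not np.isfinite(score):
        return SearchHit(target_id, NO_HIT_SCORE, [], 0.0)
    # traceback
    path = []
    state = "M"
    while True:
        path.append((k, j, state))
        prev = ptr[(state, j, k)]
        if prev == "S":
            break
        if state == "M":
            j, k = j - 1, k - 1
        elif state == "I":
            j = j - 1
        else:  # D
            k = k - 1
        state = prev
    path.reverse()
    alignment = [(int(p), int(s), st) for p, s, st in path]
    n_match = sum(1 for *_, st in alignment if st == "M")
    return SearchHit(target_id, score, alignment, n_match / L)


def _batch_scores(profile: ProfileHMM, encoded: list[np.ndarray]
                  ) -> np.ndarray:
    """Viterbi bit scores for many sequences at once (no traceback).

    Same recurrence as :func:`viterbi_search`, vectorized over the
    database; the delete chain along k is folded into a prefix-max so each
    sequence position costs O(n_seqs * L) vector work.
    """
    em, ins, tr = _score_tables(profile)
    # forbidden transitions become a huge finite penalty: -inf entries in
    # the delete-chain cumsum would otherwise produce NaN (inf - inf)
    tr = np.maximum(tr, -1e6)
    L = profile.length
    entry = -np.log2(L)
    NEG = -1e30
    n_seqs = len(encoded)
    if n_seqs == 0:
        return np.zeros(0)
    lens = np.array([len(s) for s in encoded])
    maxlen = int(lens.max(initial=0))
    if maxlen == 0:
        return np.full(n_seqs, NO_HIT_SCORE)
    X = np.full((n_seqs, maxlen), len(profile.alphabet), dtype=int)
    for i, s in enumerate(encoded):
        X[i, :len(s)] = s
    # delete-chain prefix weights: cdd[k] = sum of log2 p_dd up to node k-1
    cdd = np.concatenate([[0.0], np.cumsum(tr[:-1, 6])])
    best = np.full(n_seqs, NEG)
    M = np.full((n_seqs, L), NEG)
    I = np.full((n_seqs, L), NEG)
    D = np.full((n_seqs, L), NEG)
    for j in range(maxlen):
        e = em[:, X[:, j]].T  # (n_seqs, L)
        if j == 0:
            Mn = e + entry
            In = np.full((n_seqs, L), NEG)
        else:
            cont = np.full((n_seqs, L), NEG)
            cont[:, 1:] = np.maximum.reduce([
                M[:, :-1] + tr[:-1, 0],
                I[:, :-1] + tr[:-1, 3],
                D[:, :-1] + tr[:-1, 5],
            ])
            Mn = e + np.maximum(entry, cont)
            In = ins[:, X[:, j]].T + np.maximum(M + tr[:, 1], I + tr[:, 4])
        # delete states at position j: D[k] = max_{m<k} M[m]+t_md[m]+dd-run
        A = np.full((n_seqs, L), NEG)
        A[:, :-1] = Mn[:, :-1] + tr[:-1, 2] - cdd[1:]
        Dn = np.full((n_seqs, L), NEG)
        Dn[:, 1:] = np.maximum.accumulate(A[:, :-1], axis=1) + cdd[1:]
        M, I, D = Mn, In, Dn
        active = j < lens
        best[active] = np.maximum(best[active], M[active].max(axis=1))
    best[best <= NEG / 2] = NO_HIT_SCORE
    return best


def search_database(profile: ProfileHMM, db, top_n: int | None = None,
                    bit_threshold: float | None = None) -> list[SearchHit]:
    """Rank database sequences by Viterbi bit score against the profile.

    ``db`` is an iterable of ``(id, sequence)`` pairs or Bio.SeqRecord
    objects. Hits come back sorted by descending bit score, ties broken by
    target id; with ``bit_threshold`` set, only hits at or above it are
    reported. Alignments are computed for the reported hits only.
    """
    records = []
    for rec in db:
        if hasattr(rec, "id"):
            records.append((rec.id, str(rec.seq)))
        else:
            records.append((rec[0], str(rec[1])))
    if not records:
        raise ValueError("empty sequence database")
    valid = set(profile.alphabet)
    n_alien = sum(1 for _, s in records
                  for ch in s.upper() if ch not in valid)
    n_total = sum(len(s) for _, s in records)
    if n_total and n_alien > 0.5 * n_total:
        raise ValueError(
            "database alphabet does not match the profile alphabet")
    encoded = [_encode(s, profile.alphabet) for _, s in records]
    scores = _batch_scores(profile, encoded)
    order = sorted(range(len(records)),
                   key=lambda i: (-scores[i], records[i][0]))
    if bit_threshold is not None:
        order = [i for i in order if scores[i] >= bit_threshold]
    if top_n is not None:
        order = order[:top_n]
    hits = []
    for i in order:
        hit = viterbi_search(profile, records[i][1], records[i][0])
        hits.append(hit)
    return hits
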