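"""Protein identification workflows.

Two modes. With known input sequences, each traced chain's profile is
searched against them and matched residues are *mutated* to the identity of
the matched sequence position (known-sequence assignment). Without input
sequences, chain profiles are searched against a whole proteome; because
large complexes often contain several copies of the same protein, weak
individual hits are bootstrapped by cross-referencing: chains whose
candidate lists agree on a proteome entry are grouped and scored jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import Chain, Residue, Atom, ResiduePrediction
from .hmm import SearchHit, build_profile, search_database, DEFAULT_D

__all__ = ["ChainAssignment", "assign_chain", "identify_unknown",
           "IdentificationReport", "DEFAULT_BIT_THRESHOLD",
           "DEFAULT_MIN_FRAGMENT"]

log = logging.getLogger(__name__)

# Minimum Viterbi bit score for accepting a chain-to-sequence assignment.
# The reference workflow thresholds on HMMER E-values, whose calibration is
# delegated to external HMMER; a flat bit-score floor stands in for it.
DEFAULT_BIT_THRESHOLD = 25.0

# Fragments shorter than this are not reported in proteome-wide
# identification. Identification from fragments in the low tens of residues
# is expected to work, so the floor sits well below that.
DEFAULT_MIN_FRAGMENT = 10


@dataclass
class ChainAssignment:
    """A chain mapped onto a region of one input sequence."""

    chain_id: str
    sequence_id: str
    start: int  # 1-based inclusive residue range on the sequence
    end: int
    mapping: dict  # chain residue index (0-based) -> sequence position (1-based)
    bit_score: float

    def __post_init__(self):
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("mapping must be injective on sequence positions")
        if self.mapping:
            lo, hi = min(self.mapping.values()), max(self.mapping.values())
            if (lo, hi) != (self.start, self.end):
                raise ValueError("range bounds inconsistent with mapping")

    @property
    def range(self) -> tuple:
        return (self.start, self.end)


def _renumber(n_res: int, mapping: dict) -> list[int]:
    """Residue numbers following sequence coordinates: aligned residues
    take their matched position, unaligned ones extrapolate from the
    nearest aligned neighbour while keeping numbers strictly increasing."""
    nums = [None] * n_res
    for i, pos in mapping.items():
        nums[i] = pos
    last = None
    for i in range(n_res):
        if nums[i] is None and last is not None:
            nums[i] = last + 1
        if nums[i] is not None:
            last = nums[i]
    nxt = None
    for i in range(n_res - 1, -1, -1):
        if nums[i] is None:
            nums[i] = (nxt - 1) if nxt is not None else i + 1
        nxt = nums[i]
    for i in range(1, n_res):  # enforce strict monotonicity
        if nums[i] <= nums[i - 1]:
            nums[i] = nums[i - 1] + 1
    return nums


def assign_chain(preds: list[ResiduePrediction], hit: SearchHit | None,
                 sequences: dict, chain_id: str = "A",
                 bit_threshold: float = DEFAULT_BIT_THRESHOLD,
                 polymer: str | None = None):
    """Mutate a predicted chain to its matched sequence identities.

    Residues aligned in a match state take the identity of their matched
    sequence position and are renumbered by sequence coordinates;
    unaligned residues keep their argmax identity. Returns
    ``(assignment, chain)``; the assignment is None (and identities are
    left at argmax, with the chain flagged in the log) when there is no
    hit at or above ``bit_threshold``. Coordinates are never modified.
    """
    polymer = polymer or preds[0].polymer_class
    anchor = "CA" if polymer == "amino" else "P"
    element = "C" if polymer == "amino" else "P"

    accepted = (hit is not None and hit.bit_score >= bit_threshold
                and hit.target_id in sequences)
    if hit is not None and hit.target_id not in sequences:
        raise ValueError(
            f"hit target {hit.target_id!r} not among the input sequences")
    if not accepted:
        log.info("chain %s: no hit above %.1f bits, left unassigned",
                 chain_id, bit_threshold)
        residues = [
            Residue(i + 1, p.argmax_identity,
                    [Atom(anchor, element, p.position, p.confidence)])
            for i, p in enumerate(preds)
        ]
        return None, Chain(chain_id, polymer, residues)

    seq = str(sequences[hit.target_id])
    # hit alignment entries are (profile_pos 0-based, seq_pos 0-based, state)
    mapping = {p: s + 1 for p, s, st in hit.alignment if st == "M"}
    nums = _renumber(len(preds), mapping)
    residues = []
    for i, p in enumerate(preds):
        if i in mapping:
            identity = seq[mapping[i] - 1]
        else:
            identity = p.argmax_identity
        residues.append(Residue(
            nums[i], identity,
            [Atom(anchor, element, p.position, p.confidence)]))
    assignment = ChainAssignment(
        chain_id=chain_id, sequence_id=hit.target_id,
        start=min(mapping.values()), end=max(mapping.values()),
        mapping=mapping, bit_score=hit.bit_score)
    return assignment, Chain(chain_id, polymer, residues)


@dataclass
class IdentificationReport:
    """Ranked per-chain candidates plus cross-referenced groups."""

    per_chain: dict = field(default_factory=dict)  # chain_id -> [SearchHit]
    groups: list = field(default_factory=list)  # (target_id, [chain_ids], combined)
    skipped: list = field(default_factory=list)  # chains below min_fragment
    identified: bool = False

    @property
    def best_target(self) -> str | None:
        return self.groups[0][0] if self.groups else None

    def to_tsv(self) -> str:
        lines = ["chain\trank\ttarget\tbit_score\tcoverage"]
        for cid in sorted(self.per_chain):
            for rank, h in enumerate(self.per_chain[cid], start=1):
                lines.append(
                    f"{cid}\t{rank}\t{h.target_id}\t{h.bit_score:.2f}"
                    f"\t{h.coverage:.3f}")
        lines.append("")
        lines.append("group_target\tchains\tcombined_bit_score")
        for target, cids, score in self.groups:
            lines.append(f"{target}\t{','.join(cids)}\t{score:.2f}")
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        if not self.identified:
            return ("No proteome entry passed the acceptance threshold; "
                    "chains remain unidentified.\n")
        out = []
        for target, cids, score in self.groups:
            out.append(f"{target}: chains {', '.join(cids)} "
                       f"(combined {score:.1f} bits)")
        return "\n".join(out) + "\n"


def identify_unknown(chains: dict, proteome,
                     min_fragment: int = DEFAULT_MIN_FRAGMENT,
                     bit_threshold: float = DEFAULT_BIT_THRESHOLD,
                     top_n: int = 5, d: float = DEFAULT_D,
                     try_reversed: bool = False) -> IdentificationReport:
    """Identify unknown chains against a proteome.

    ``chains`` maps chain id to its list of residue predictions (identity
    probabilities and confidences only — no input-sequence knowledge is
    used). Each chain of at least ``min_fragment`` residues is converted
    to a profile HMM and searched against the proteome; chains whose
    top-``top_n`` candidate lists share a proteome entry are grouped, the
    group scored by the sum of its chains' bit scores for that entry.
    Groups whose combined score reaches ``bit_threshold`` are reported in
    descending combined score (ties by target id). Deterministic for fixed
    inputs. With ``try_reversed``, each chain is also searched back-to-
    front and the better orientation kept (for fragments traced with
    unknown chain direction).
    """
    records = [(r.id, str(r.seq)) if hasattr(r, "id") else (r[0], str(r[1]))
               for r in proteome]
    if not records:
        raise ValueError("empty proteome")

    report = IdentificationReport()
    for cid in sorted(chains):
        preds = chains[cid]
        if len(preds) < min_fragment:
            report.skipped.append(cid)
            continue
        profile = build_profile(preds, d=d, name=cid)
        hits = search_database(profile, records, top_n=top_n)
        if try_reversed:
            rev_hits = search_database(profile.reversed(), records,
                                       top_n=top_n)
            best_f = hits[0].bit_score if hits else float("-inf")
            best_r = rev_hits[0].bit_score if rev_hits else float("-inf")
            if best_r > best_f:
                hits = rev_hits
        report.per_chain[cid] = hits

    combined: dict[str, list] = {}
    for cid, hits in report.per_chain.items():
        for h in hits:
            combined.setdefault(h.target_id, []).append((cid, h.bit_score))
    groups = []
    for target, members in combined.items():
        best_per_chain: dict[str, float] = {}
        for cid, s in members:
            best_per_chain[cid] = max(best_per_chain.get(cid, -1e30), s)
        score = sum(best_per_chain.values())
        groups.append((target, sorted(best_per_chain), score))
    groups = [g for g in groups if g[2] >= bit_threshold]
    groups.sort(key=lambda g: (-g[2], g[0]))
    report.groups = groups
    report.identified = bool(groups)
    return report
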