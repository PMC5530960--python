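"""Encoding residue pairs at two alignment positions as a four-state character.

Two binary traits are read off a masked alignment: trait X is 1 when the
residue at its focal position belongs to a configured residue set (e.g. the
phospho-acceptor set {S, T}), and trait Y likewise (e.g. the sulfoxidable
{M}). The ordered pair (X, Y) is packed into a single four-state character:

    state 1 = (0,0)   state 2 = (0,1)   state 3 = (1,0)   state 4 = (1,1)

Tips with a gap or unknown residue at either focal position are AMBIGUOUS and
contribute a flat (all-ones) partial likelihood downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .phylo import Alignment, MISSING_CHARS

#: Sentinel state for tips whose residue at either focal position is missing.
AMBIGUOUS: int = 0

#: states 1..4 as ordered (X, Y) pairs
STATE_PAIRS: Dict[int, Tuple[int, int]] = {1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)}

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TraitDefinition:
    """A binary trait: a 1-based reference position and the residues scored 1."""

    position: int
    state1_residues: frozenset

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        residues = frozenset(str(r).upper() for r in self.state1_residues)
        if not residues:
            raise ValueError("state1_residues must be non-empty")
        bad = residues - _VALID_AA
        if bad:
            raise ValueError(f"not amino acids: {sorted(bad)}")
        object.__setattr__(self, "state1_residues", residues)

    @classmethod
    def from_string(cls, text: str) -> "TraitDefinition":
        """Parse ``"218:ST"``-style definitions (position, residue string)."""
        pos_s, _, res = text.partition(":")
        return cls(position=int(pos_s), state1_residues=frozenset(res))

    def score(self, residue: str) -> int:
        return int(residue.upper() in self.state1_residues)


def encode_traits(
    alignment: Alignment,
    x: TraitDefinition,
    y: TraitDefinition,
    drop_ambiguous: bool = False,
) -> Dict[str, int]:
    """Combined tip states from a reference-masked alignment.

    ``alignment`` must already be masked to the reference (columns = ungapped
    reference positions). Returns a label -> state map with states in
    {1, 2, 3, 4} or :data:`AMBIGUOUS`; with ``drop_ambiguous`` the ambiguous
    tips are omitted instead.
    """
    L = alignment.length
    for pos in (x.position, y.position):
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} out of range 1..{L}")
    states: Dict[str, int] = {}
    for label, seq in alignment.records:
        rx = seq[x.position - 1].upper()
        ry = seq[y.position - 1].upper()
        if rx in MISSING_CHARS or ry in MISSING_CHARS:
            if not drop_ambiguous:
                states[label] = AMBIGUOUS
            continue
        states[label] = 1 + 2 * x.score(rx) + y.score(ry)
    return states


def swap_traits(states: Dict[str, int]) -> Dict[str, int]:
    """Relabel combined states as if the two traits were given in the other
    order: the ordered pair is transposed, exchanging states 2 and 3."""
    swap = {AMBIGUOUS: AMBIGUOUS, 1: 1, 2: 3, 3: 2, 4: 4}
    return {k: swap[v] for k, v in states.items()}


def control_sets() -> List[Tuple[frozenset, frozenset]]:
    """The positive residue-set pair plus the 16 control definitions.

    The first entry is the positive pair (phospho-acceptors {S,T} against the
    sulfoxidable {M}); the remaining 16 are unrelated residue-set pairs used
    to show that the coevolution signal is specific to the modifiable
    residues: same X set with non-sulfoxidable Y ({V},{C},{N},{L}); paired
    non-phospho-acceptor X sets with {M}; the same X sets with {V}; and four
    arbitrary pairs.
    """
    fs = frozenset
    sets: List[Tuple[frozenset, frozenset]] = [(fs("ST"), fs("M"))]
    sets += [(fs("ST"), fs(y)) for y in ("V", "C", "N", "L")]
    xsets = [fs("NQ"), fs("GA"), fs("DE"), fs("HK")]
    sets += [(xs, fs("M")) for xs in xsets]
    sets += [(xs, fs("V")) for xs in xsets]
    sets += [
        (fs("QP"), fs("G")),
        (fs("WV"), fs("A")),
        (fs("LT"), fs("I")),
        (fs("IY"), fs("H")),
    ]
    return sets


def observed_state_frequencies(states: Dict[str, int]):
    """Empirical frequencies of states 1..4 among unambiguous tips."""
    import numpy as np

    counts = np.zeros(4)
    for s in states.values():
        if s != AMBIGUOUS:
            counts[s - 1] += 1
    if counts.sum() == 0:
        raise ValueError("all tips are ambiguous; no observed frequencies")
    return counts / counts.sum()
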