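"""RNA secondary structures as nested base-pair sets.

Coordinates are 1-based and inclusive throughout the package.  A structure
is a set of pairs ``(i, j)`` with ``i < j``; pseudoknots (crossing pairs)
are outside the model, so every structure maps bijectively onto a balanced
dot-bracket string using ``()`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "SecondaryStructure",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "partner_array",
    "pairs_are_nested",
]

WATSON_CRICK_WOBBLE = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)


class StructureError(ValueError):
    """Raised for malformed pair sets or dot-bracket strings."""


def _canonical_pairs(pairs: Iterable[Sequence[int]]) -> tuple[tuple[int, int], ...]:
    out = []
    for p in pairs:
        i, j = int(p[0]), int(p[1])
        if i == j:
            raise StructureError(f"self-pair at position {i}")
        if i > j:
            i, j = j, i
        out.append((i, j))
    return tuple(sorted(out))


def pairs_are_nested(pairs: Iterable[tuple[int, int]]) -> bool:
    """True iff no two pairs cross (i < k < j < l)."""
    ps = sorted(pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if k > j:
                break
            if i < k <= j < l:
                return False
    return True


def partner_array(pairs: Iterable[tuple[int, int]], n: int) -> list[int]:
    """Partner of each 1-based position (index 0 unused); 0 means unpaired."""
    partner = [0] * (n + 1)
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise StructureError(f"pair ({i},{j}) outside sequence of length {n}")
        if partner[i] or partner[j]:
            raise StructureError(f"position in more than one pair: ({i},{j})")
        partner[i], partner[j] = j, i
    return partner


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], n: int) -> str:
    pairs = _canonical_pairs(pairs)
    if not pairs_are_nested(pairs):
        raise StructureError("crossing pairs cannot be written as dot-bracket")
    partner = partner_array(pairs, n)
    out = []
    for pos in range(1, n + 1):
        if partner[pos] == 0:
            out.append(".")
        elif partner[pos] > pos:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def dotbracket_to_pairs(text: str) -> tuple[tuple[int, int], ...]:
    """Parse ``()`` dot-bracket notation; errors carry the 1-based position."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(
            f"unbalanced '(' opened at position {stack[-1]}; string ends at position {len(text)}"
        )
    return tuple(sorted(pairs))


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure over an RNA sequence.

    Parameters
    ----------
    sequence
        RNA string over {A, C, G, U}.
    pairs
        Base pairs as 1-based ``(i, j)`` tuples with ``i < j``.
    energy
        Optional free energy in kcal/mol (populated by the folding engine).
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", _canonical_pairs(self.pairs))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)

    def partner(self) -> list[int]:
        return partner_array(self.pairs, len(self.sequence))

    def validate(
        self,
        min_hairpin: int = 3,
        max_pairing_dist: Optional[int] = None,
        check_complementarity: bool = True,
    ) -> None:
        """Raise :class:`StructureError` listing every violated invariant."""
        n = len(self.sequence)
        problems: list[str] = []
        try:
            partner_array(self.pairs, n)
        except StructureError as exc:
            problems.append(str(exc))
        if not pairs_are_nested(self.pairs):
            problems.append("pairs are not nested (pseudoknot)")
        for i, j in self.pairs:
            if j - i < min_hairpin + 1:
                problems.append(f"pair ({i},{j}) closes a loop shorter than {min_hairpin}")
            if max_pairing_dist is not None and j - i > max_pairing_dist:
                problems.append(f"pair ({i},{j}) exceeds maxPairingDist {max_pairing_dist}")
            if check_complementarity and 1 <= i <= n and 1 <= j <= n:
                duo = (self.sequence[i - 1], self.sequence[j - 1])
                if duo not in WATSON_CRICK_WOBBLE:
                    problems.append(f"pair ({i},{j}) is non-canonical {duo[0]}-{duo[1]}")
        if problems:
            raise StructureError("; ".join(problems))

    def to_dotbracket(self) -> str:
        return pairs_to_dotbracket(self.pairs, len(self.sequence))

    @classmethod
    def from_dotbracket(cls, sequence: str, dotbracket: str,
                        energy: Optional[float] = None) -> "SecondaryStructure":
        if len(sequence) != len(dotbracket):
            raise StructureError(
                f"sequence length {len(sequence)} != dot-bracket length {len(dotbracket)}"
            )
        return cls(sequence=sequence, pairs=dotbracket_to_pairs(dotbracket), energy=energy)

    def remove_pairs(self, drop: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        drop_set = {tuple(sorted(p)) for p in drop}
        return SecondaryStructure(
            sequence=self.sequence,
            pairs=tuple(p for p in self.pairs if p not in drop_set),
            energy=None,
        )
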