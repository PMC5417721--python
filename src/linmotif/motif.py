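"""Motif pattern language: defined, wildcard and bracketed (degenerate) positions.

A motif is a fixed-length pattern over the 20 canonical amino acids.  Each
position is one of

* ``Defined(aa)`` -- matches exactly one amino acid, e.g. ``P``;
* ``Wildcard``   -- matches any canonical amino acid, rendered ``x``;
* ``Bracket``    -- matches a set of 2..19 amino acids, e.g. ``[LV]``.

Non-canonical residues (``B J O U X Z *`` and anything else outside the
20-letter alphabet) are *sentinels*: they match nothing, not even a wildcard,
so ambiguity codes can never inflate motif counts.

The text dialect accepts ``x``, ``X`` or ``.`` for wildcards on input and
always renders ``x`` on output; bracket contents render in alphabetical
order, making the rendering canonical (equal motifs render identically).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

#: residue code used internally for any non-canonical letter
SENTINEL = 20

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_MAX_LENGTH = 15

_WILDCARD_CHARS = {"x", "X", "."}


class MotifError(ValueError):
    """Raised for malformed motif text or invalid motif construction."""


class Wildcard:
    """Singleton marker for an unconstrained position."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - debugging aid
        return "Wildcard"


WILDCARD = Wildcard()

# A position is a single amino-acid letter (defined), the WILDCARD marker, or
# a frozenset of letters (bracket).  Canonicalization guarantees brackets have
# 2..19 members.
PositionSpec = Union[str, Wildcard, frozenset]


def _canonical_position(pos: PositionSpec) -> PositionSpec:
    if isinstance(pos, frozenset):
        bad = pos - AA_SET
        if bad:
            raise MotifError(f"non-canonical letters in bracket: {sorted(bad)}")
        if len(pos) == 0:
            raise MotifError("empty bracket")
        if len(pos) == 1:
            return next(iter(pos))
        if len(pos) == 20:
            return WILDCARD
        return pos
    if isinstance(pos, Wildcard):
        return WILDCARD
    if isinstance(pos, str):
        if pos not in AA_SET:
            raise MotifError(f"not a canonical amino acid: {pos!r}")
        return pos
    raise MotifError(f"invalid position spec: {pos!r}")


@dataclass(frozen=True)
class Motif:
    """Fixed-length motif; immutable and hashable by its positions."""

    positions: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "positions", tuple(_canonical_position(p) for p in self.positions)
        )
        if len(self.positions) < 2:
            raise MotifError(
                f"motif must have at least 2 positions, got {len(self.positions)}"
            )
        if len(self.positions) > DEFAULT_MAX_LENGTH:
            raise MotifError(
                f"motif longer than the {DEFAULT_MAX_LENGTH}-position maximum"
            )

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def is_canonical(self) -> bool:
        """True iff the first and last positions are not wildcards.

        A motif with a terminal wildcard is count-equivalent to a shorter
        motif, so canonical-mode enumeration never produces one; strict mode
        (all 2^l masks) may.
        """
        return not (
            isinstance(self.positions[0], Wildcard)
            or isinstance(self.positions[-1], Wildcard)
        )

    def wildcard_positions(self) -> tuple:
        return tuple(
            i for i, p in enumerate(self.positions) if isinstance(p, Wildcard)
        )

    def n_wildcards(self) -> int:
        return len(self.wildcard_positions())

    # -- text form -----------------------------------------------------------

    def render(self) -> str:
        out = []
        for p in self.positions:
            if isinstance(p, Wildcard):
                out.append("x")
            elif isinstance(p, frozenset):
                out.append("[" + "".join(sorted(p)) + "]")
            else:
                out.append(p)
        return "".join(out)

    def __str__(self) -> str:
        return self.render()

    # -- matching ------------------------------------------------------------

    def matches_at(self, residues: str, offset: int) -> bool:
        """True iff the motif matches ``residues`` starting at ``offset``.

        Sentinel residues in the window fail every position, wildcards
        included.
        """
        l = len(self.positions)
        if offset < 0 or offset > len(residues) - l:
            raise MotifError(
                f"offset {offset} out of range for length-{len(residues)} sequence"
            )
        for i, p in enumerate(self.positions):
            c = residues[offset + i]
            if c not in AA_SET:
                return False
            if isinstance(p, Wildcard):
                continue
            if isinstance(p, frozenset):
                if c not in p:
                    return False
            elif c != p:
                return False
        return True

    def match_offsets(self, residues: str) -> list:
        """All offsets at which the motif matches (overlaps allowed)."""
        l = len(self.positions)
        return [
            off
            for off in range(len(residues) - l + 1)
            if self.matches_at(residues, off)
        ]

    def to_regex(self) -> str:
        """POSIX-style character-class regular expression for this motif.

        The wildcard is exported as the canonical 20-letter class (not ``.``)
        so sentinel residues cannot match it.
        """
        out = []
        for p in self.positions:
            if isinstance(p, Wildcard):
                out.append("[" + AMINO_ACIDS + "]")
            elif isinstance(p, frozenset):
                out.append("[" + "".join(sorted(p)) + "]")
            else:
                out.append(p)
        return "".join(out)

    def compiled(self) -> "re.Pattern":
        return re.compile("(?=" + self.to_regex() + ")")


def parse_motif(text: str) -> Motif:
    """Parse motif text such as ``Px[LV]PxK``.

    ``x``, ``X`` and ``.`` are wildcards on input; ``[...]`` encloses a
    bracket.  Errors carry the 1-based column of the offending character.
    """
    positions = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c in _WILDCARD_CHARS:
            positions.append(WILDCARD)
            i += 1
        elif c == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise MotifError(f"unclosed bracket at column {i + 1}")
            inner = text[i + 1 : j]
            if not inner:
                raise MotifError(f"empty bracket at column {i + 1}")
            letters = set()
            for k, ch in enumerate(inner):
                up = ch.upper()
                if up not in AA_SET:
                    raise MotifError(
                        f"illegal character {ch!r} at column {i + 2 + k}"
                    )
                letters.add(up)
            positions.append(frozenset(letters))
            i = j + 1
        else:
            up = c.upper()
            if up not in AA_SET:
                raise MotifError(f"illegal character {c!r} at column {i + 1}")
            positions.append(up)
            i += 1
    return Motif(tuple(positions))


def render_motif(m: Motif) -> str:
    return m.render()


def motif_matches_at(m: Motif, residues: str, offset: int) -> bool:
    return m.matches_at(residues, offset)


@dataclass(frozen=True)
class Mask:
    """Boolean wildcard pattern over motif positions (True = wildcard)."""

    pattern: tuple

    def __post_init__(self):
        object.__setattr__(self, "pattern", tuple(bool(b) for b in self.pattern))
        if len(self.pattern) < 2:
            raise MotifError("mask must cover at least 2 positions")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def is_canonical(self) -> bool:
        return not (self.pattern[0] or self.pattern[-1])

    def __iter__(self) -> Iterator[bool]:
        return iter(self.pattern)

    def __str__(self) -> str:
        return "".join("x" if b else "-" for b in self.pattern)


def apply_mask(peptide: str, mask: Mask) -> Motif | None:
    """Turn an l-mer into a motif: masked positions become wildcards.

    Returns None (rejection) when a sentinel residue sits at a non-masked
    position, since no defined position can carry a non-canonical letter.
    """
    if len(peptide) != len(mask):
        raise MotifError(
            f"peptide length {len(peptide)} != mask length {len(mask)}"
        )
    positions = []
    for c, masked in zip(peptide.upper(), mask):
        if masked:
            positions.append(WILDCARD)
        else:
            if c not in AA_SET:
                return None
            positions.append(c)
    return Motif(tuple(positions))


def encode_residues(residues: str) -> "np.ndarray":
    """Encode a residue string as uint8 codes (0..19 canonical, 20 sentinel)."""
    import numpy as np

    codes = _ENCODE_TABLE[np.frombuffer(residues.encode("ascii", "replace"), dtype=np.uint8)]
    return codes


def _build_encode_table():
    import numpy as np

    table = np.full(256, SENTINEL, dtype=np.uint8)
    for aa, i in AA_INDEX.items():
        table[ord(aa)] = i
        table[ord(aa.lower())] = i
    return table


_ENCODE_TABLE = _build_encode_table()
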