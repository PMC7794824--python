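"""Degenerate motif patterns and exact window scanning.

The MYC-interaction motif (MIM) is the hexamer ``[L/F]LN[K/R][V/L]A`` whose
core positions (L, N, A at motif positions 2, 3 and 6) are absolutely required
for binding.  Three built-in patterns cover the tolerance levels used in
practice:

``core``
    ``xLNxxA`` — only the required positions constrained.
``strict``
    ``[LF]LN[KR][VL]A`` — the full motif consensus.
``phi``
    ``[LVFI]LN[KR][IFLV]A`` — the relaxed pattern used for similarity
    searches.

Because each position's allowed set is nested across the three patterns,
hits(strict) is a subset of hits(phi), which is a subset of hits(core) on any
sequence.  All hits are reported, including overlapping ones, since proteins
may carry several motif instances.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Optional, Union

from .sequence_io import CANONICAL_RESIDUES, MASK, SequenceRecord

__all__ = [
    "MotifPattern",
    "MotifHit",
    "builtin_patterns",
    "get_pattern",
    "parse_pattern",
    "scan",
    "map_to_protein",
]

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class MotifPattern:
    """Per-position allowed residue sets, with core positions marked.

    ``positions`` entries are frozensets of allowed residues, or ``None`` for
    "any canonical residue".  ``core_mask`` flags the absolutely required
    positions (a subset of the constrained positions).
    """

    name: str
    positions: tuple[Optional[frozenset], ...]
    core_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError("a motif pattern must have length >= 3")
        if len(self.core_mask) != len(self.positions):
            raise ValueError("core_mask length must match pattern length")
        for i, allowed in enumerate(self.positions):
            if allowed is None:
                if self.core_mask[i]:
                    raise ValueError("core positions must be constrained (non-'any')")
                continue
            if not allowed or not allowed <= _CANONICAL_SET:
                raise ValueError(
                    f"position {i + 1}: allowed set must be a non-empty subset "
                    "of the canonical residues"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        """True if every residue of ``window`` lies in its allowed set.

        Masked residues (``X``) never match any position, including "any".
        """
        if len(window) != len(self.positions):
            return False
        for residue, allowed in zip(window, self.positions):
            if allowed is None:
                if residue not in _CANONICAL_SET:
                    return False
            elif residue not in allowed:
                return False
        return True

    def to_text(self) -> str:
        """Render back to bracket syntax, e.g. ``[LF]LN[KR][VL]A``."""
        parts = []
        for allowed in self.positions:
            if allowed is None:
                parts.append("x")
            elif len(allowed) == 1:
                parts.append(next(iter(allowed)))
            else:
                parts.append("[" + "".join(sorted(allowed)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """A motif match; ``start``/``end`` are 1-based and inclusive."""

    sequence_id: str
    start: int
    end: int
    matched_span: str
    pattern_name: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_span):
            raise ValueError("hit span length inconsistent with start/end")


def _pattern(name: str, spec: list[Optional[str]], core: tuple[int, ...]) -> MotifPattern:
    positions = tuple(None if s is None else frozenset(s) for s in spec)
    mask = tuple(i + 1 in core for i in range(len(spec)))
    return MotifPattern(name=name, positions=positions, core_mask=mask)


_CORE_POSITIONS = (2, 3, 6)  # L, N, A

_BUILTINS = {
    "core": _pattern("core", [None, "L", "N", None, None, "A"], _CORE_POSITIONS),
    "strict": _pattern("strict", ["LF", "L", "N", "KR", "VL", "A"], _CORE_POSITIONS),
    "phi": _pattern("phi", ["LVFI", "L", "N", "KR", "IFLV", "A"], _CORE_POSITIONS),
}


def builtin_patterns() -> list[MotifPattern]:
    """Return the three built-in MIM patterns: core, strict, phi."""
    return [_BUILTINS["core"], _BUILTINS["strict"], _BUILTINS["phi"]]


_TOKEN_RE = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z])")


def parse_pattern(text: str, name: Optional[str] = None) -> MotifPattern:
    """Parse bracket syntax (``[LF]LN[KR][VL]A``; ``x`` = any) into a pattern.

    Case-insensitive.  For user-supplied patterns the core mask marks the
    single-residue positions (the positions the pattern pins down exactly).
    """
    positions: list[Optional[frozenset]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse pattern {text!r} at offset {pos}")
        pos = m.end()
        if m.group(1) is not None:
            allowed = frozenset(m.group(1).upper())
        else:
            letter = m.group(2).upper()
            allowed = None if letter == "X" else frozenset(letter)
        positions.append(allowed)
    if pos != len(text):
        raise ValueError(f"cannot parse pattern {text!r} at offset {pos}")
    core = tuple(allowed is not None and len(allowed) == 1 for allowed in positions)
    return MotifPattern(name=name or text, positions=tuple(positions), core_mask=core)


def get_pattern(name_or_text: str) -> MotifPattern:
    """Look up a built-in pattern by name, or parse ``name_or_text`` as syntax."""
    key = name_or_text.lower()
    if key in _BUILTINS:
        return _BUILTINS[key]
    return parse_pattern(name_or_text)


def scan(sequence: Union[SequenceRecord, str], pattern: MotifPattern) -> list[MotifHit]:
    """Return every window of ``sequence`` matching ``pattern``, sorted by start.

    Hits may overlap.  A sequence shorter than the pattern yields an empty
    list.  Masked (``X``) residues never take part in a match.
    """
    if isinstance(sequence, SequenceRecord):
        residues, seq_id = sequence.residues, sequence.identifier
    else:
        residues, seq_id = str(sequence), "query"
    n, m = len(residues), len(pattern)
    hits = []
    for start0 in range(n - m + 1):
        window = residues[start0:start0 + m]
        if pattern.matches(window):
            hits.append(MotifHit(sequence_id=seq_id, start=start0 + 1,
                                 end=start0 + m, matched_span=window,
                                 pattern_name=pattern.name))
    return hits


def map_to_protein(hit: MotifHit, peptide_start_in_protein: int) -> MotifHit:
    """Shift a peptide-local hit into protein coordinates.

    ``peptide_start_in_protein`` is the 1-based protein position of the
    peptide's first residue; the matched span is unchanged.
    """
    if peptide_start_in_protein < 1:
        raise ValueError("peptide_start_in_protein must be >= 1")
    offset = peptide_start_in_protein - 1
    return dataclasses.replace(hit, start=hit.start + offset, end=hit.end + offset)
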