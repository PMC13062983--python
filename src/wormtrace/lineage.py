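"""Sulston nomenclature engine.

Embryonic *C. elegans* cells carry names built from a founder-cell prefix
(AB, MS, E, C, D, P0..P4, EMS, Z2, Z3) followed by a string of division
letters, one per division, drawn from ``a/p`` (anterior/posterior),
``l/r`` (left/right) and ``d/v`` (dorsal/ventral).  ``ABalp`` is thus the
posterior daughter of the left daughter of the anterior daughter of AB.
This module provides name validation, parent/daughter algebra, ancestry
tests, single-letter wildcard patterns (``Cxp`` = any posterior C
granddaughter) and set selection over observed cells.

Names that do not parse (``polar body``, ``Nuc123``) are *literal labels*:
they are retained in tables and plots but excluded from lineage algebra;
queries on them return the :data:`UNKNOWN` sentinel rather than raising.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Union

FOUNDERS = ("P0", "P1", "P2", "P3", "P4", "AB", "EMS", "MS", "E", "C", "D", "Z2", "Z3")

DIVISION_LETTERS = "aplrdv"

#: Parent of each founder in the early (pre-letter) division chain.
FOUNDER_PARENT = {
    "AB": "P0", "P1": "P0",
    "EMS": "P1", "P2": "P1",
    "MS": "EMS", "E": "EMS",
    "C": "P2", "P3": "P2",
    "D": "P3", "P4": "P3",
    "Z2": "P4", "Z3": "P4",
}

#: Daughters of the founders that divide by name substitution rather than by
#: appending a division letter.  Z2/Z3 are terminal germline precursors in the
#: embryo.  Founders absent from this table (AB, MS, E, C, D) divide by
#: appending division letters.
FOUNDER_DAUGHTERS = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
    "Z2": (),
    "Z3": (),
}

# Longest-prefix parsing order ("EMS" must win over "E").
_FOUNDERS_BY_LENGTH = sorted(FOUNDERS, key=len, reverse=True)

# Canonical sibling order: a<p, l<r, d<v; founder pairs as listed in
# FOUNDER_DAUGHTERS (first daughter sorts first).
_LETTER_RANK = {"a": 0, "p": 1, "l": 0, "r": 1, "d": 0, "v": 1}


class _Unknown:
    """Sentinel for queries on literal (non-Sulston) labels."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNKNOWN"

    def __bool__(self):
        return False


UNKNOWN = _Unknown()


@dataclass(frozen=True)
class LineageName:
    """A validated cell name: founder prefix + division-letter suffix, or a
    literal label (``founder is None``)."""

    text: str
    founder: Optional[str]
    suffix: str

    @property
    def is_literal(self) -> bool:
        return self.founder is None

    @property
    def depth(self) -> int:
        """Number of letter divisions since the founder (0 for founders and
        literals)."""
        return len(self.suffix)

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class LineagePattern:
    """A cell-selection pattern: founder prefix + suffix over division letters
    plus ``x``, which matches exactly one division letter."""

    text: str
    founder: str
    suffix: str

    def __str__(self) -> str:
        return self.text


NameLike = Union[str, LineageName]
PatternLike = Union[str, LineagePattern]


@lru_cache(maxsize=65536)
def parse_name(text: str) -> LineageName:
    """Parse ``text`` into a :class:`LineageName`.

    The founder prefix is the longest founder matching the start of the
    string whose remainder consists only of division letters; anything else
    is a literal label.
    """
    text = str(text)
    for founder in _FOUNDERS_BY_LENGTH:
        if text.startswith(founder):
            suffix = text[len(founder):]
            if all(ch in DIVISION_LETTERS for ch in suffix):
                return LineageName(text, founder, suffix)
    return LineageName(text, None, "")


@lru_cache(maxsize=8192)
def parse_pattern(text: str) -> LineagePattern:
    """Parse a wildcard pattern; raises ``ValueError`` on malformed input."""
    text = str(text)
    if not text:
        raise ValueError("empty lineage pattern")
    for founder in _FOUNDERS_BY_LENGTH:
        if text.startswith(founder):
            suffix = text[len(founder):]
            if all(ch in DIVISION_LETTERS + "x" for ch in suffix):
                return LineagePattern(text, founder, suffix)
    raise ValueError(
        f"pattern {text!r} does not start with a founder prefix "
        f"({', '.join(FOUNDERS)}) followed by letters from "
        f"'{DIVISION_LETTERS}' or 'x'"
    )


def _as_name(name: NameLike) -> LineageName:
    return name if isinstance(name, LineageName) else parse_name(name)


def _as_pattern(pattern: PatternLike) -> LineagePattern:
    return pattern if isinstance(pattern, LineagePattern) else parse_pattern(pattern)


def parent_of(name: NameLike):
    """Parent cell of ``name``.

    Returns ``None`` for the zygote P0, :data:`UNKNOWN` for literal labels,
    otherwise a :class:`LineageName`.  Suffixed names drop their last
    division letter; founders use the fixed early-lineage table.
    """
    n = _as_name(name)
    if n.is_literal:
        return UNKNOWN
    if n.suffix:
        return parse_name(n.text[:-1])
    parent = FOUNDER_PARENT.get(n.founder)
    return None if parent is None else parse_name(parent)


def daughters_of(name: NameLike, observed: Optional[Iterable[str]] = None):
    """Daughters of ``name``.

    With ``observed`` (an iterable of cell-name strings), returns the observed
    names whose :func:`parent_of` is ``name``.  Without it, returns the
    nomenclaturally *potential* daughters: the founder table for P0..P4 and
    EMS, the empty tuple for Z2/Z3, and the six single-letter extensions for
    every other parseable name.  Literal labels yield :data:`UNKNOWN`.
    """
    n = _as_name(name)
    if n.is_literal:
        return UNKNOWN
    if observed is not None:
        out = []
        for obs in observed:
            o = _as_name(obs)
            p = parent_of(o)
            if isinstance(p, LineageName) and p.text == n.text:
                out.append(o)
        return tuple(sorted(out, key=lambda d: sort_key(d)))
    if not n.suffix and n.founder in FOUNDER_DAUGHTERS:
        return tuple(parse_name(d) for d in FOUNDER_DAUGHTERS[n.founder])
    return tuple(parse_name(n.text + letter) for letter in DIVISION_LETTERS)


def is_descendant(name: NameLike, ancestor: NameLike, inclusive: bool = True) -> bool:
    """True iff repeatedly taking :func:`parent_of` from ``name`` reaches
    ``ancestor``.  Literal labels warn and return False."""
    n, a = _as_name(name), _as_name(ancestor)
    if n.is_literal or a.is_literal:
        warnings.warn(
            f"ancestry query on literal label ({n.text!r} vs {a.text!r}) "
            "always returns False",
            stacklevel=2,
        )
        return False
    if inclusive and n.text == a.text:
        return True
    current = parent_of(n)
    while isinstance(current, LineageName):
        if current.text == a.text:
            return True
        current = parent_of(current)
    return False


def match_pattern(name: NameLike, pattern: PatternLike) -> bool:
    """True iff ``name`` matches ``pattern``: identical founder prefixes and
    equal-length suffixes with ``x`` matching any single division letter."""
    n = _as_name(name)
    p = _as_pattern(pattern)
    if n.is_literal or n.founder != p.founder:
        return False
    if len(n.suffix) != len(p.suffix):
        return False
    return all(pc == "x" or pc == nc for nc, pc in zip(n.suffix, p.suffix))


def pattern_regex(pattern: PatternLike) -> "re.Pattern[str]":
    """Regex equivalent of a pattern (used as an independent cross-check)."""
    p = _as_pattern(pattern)
    body = re.escape(p.founder) + "".join(
        f"[{DIVISION_LETTERS}]" if ch == "x" else re.escape(ch) for ch in p.suffix
    )
    return re.compile("^" + body + "$")


def select_cells(
    table_or_names,
    patterns: Iterable[PatternLike],
    include_descendants: bool = False,
) -> set:
    """Observed cell names matching any pattern, optionally plus all their
    observed descendants.

    ``table_or_names`` may be an ``EmbryoTable`` or any iterable of name
    strings.  A pattern that matches nothing contributes the empty set with a
    warning.  Deterministic and order-independent.
    """
    if hasattr(table_or_names, "data"):
        observed = [str(c) for c in table_or_names.data["cell"].unique()]
    else:
        observed = [str(c) for c in table_or_names]
    observed = sorted(set(observed))
    selected: set = set()
    for pat in patterns:
        p = _as_pattern(pat)
        hits = {name for name in observed if match_pattern(name, p)}
        if not hits:
            warnings.warn(f"pattern {p.text!r} matched no observed cell", stacklevel=2)
        selected |= hits
    if include_descendants and selected:
        anchors = [parse_name(s) for s in sorted(selected)]
        for name in observed:
            n = parse_name(name)
            if n.is_literal:
                continue
            if any(is_descendant(n, a) for a in anchors):
                selected.add(name)
    return selected


def sort_key(name: NameLike):
    """Key implementing the canonical lineage-chart order (a<p, l<r, d<v;
    AB<P1, EMS<P2, MS<E, C<P3, D<P4, Z2<Z3).  Literal labels sort last,
    alphabetically."""
    n = _as_name(name)
    if n.is_literal:
        return (1, (), n.text)
    ranks = []
    current: Optional[LineageName] = n
    while current is not None and current.text != "P0":
        parent = parent_of(current)
        if not isinstance(parent, LineageName):
            break
        if current.suffix:
            ranks.append(_LETTER_RANK[current.suffix[-1]])
        else:
            pair = FOUNDER_DAUGHTERS.get(parent.founder, ())
            ranks.append(pair.index(current.founder) if current.founder in pair else 0)
        current = parent
    return (0, tuple(reversed(ranks)), n.text)
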