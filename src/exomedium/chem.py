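"""Molecular formulas and elemental bookkeeping.

Every mass computed by this package traces back to the atomic-weight table
bundled here (IUPAC standard atomic weights, conventional values, at most
four decimals), so recipes and stoichiometry reports are reproducible
bit-for-bit across machines. The table version is exported so reports can
embed it in their headers.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from typing import Iterator

ATOMIC_WEIGHT_VERSION = "IUPAC-2021-conventional-4dp"

#: Standard atomic weights (g/mol), conventional single values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Co": 58.933,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.38,
    "Se": 78.971,
    "Br": 79.904,
    "Mo": 95.95,
    "I": 126.904,
}


class FormulaError(ValueError):
    """Base class for molecular-formula parse and mass errors."""


class UnknownElementError(FormulaError):
    """An element symbol is not in the bundled atomic-weight table."""


class MalformedCountError(FormulaError):
    """An atom or group count is not a positive integer."""


class UnbalancedParenthesesError(FormulaError):
    """Parentheses in the formula do not pair up."""


class ElementTally(Mapping):
    """Immutable element -> atom-count mapping for one formula unit.

    Counts are strictly positive integers and at least one element must be
    present. Serialization follows Hill order: C first, H second, then the
    remaining elements alphabetically (all-alphabetical when no carbon).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        items = dict(counts)
        if not items:
            raise FormulaError("element tally must contain at least one element")
        for el, c in items.items():
            if not re.fullmatch(r"[A-Z][a-z]?", el):
                raise FormulaError(f"invalid element symbol {el!r}")
            if isinstance(c, bool) or not isinstance(c, (int,)) or c < 1:
                raise MalformedCountError(f"count for {el} must be a positive integer, got {c!r}")
        object.__setattr__(self, "_counts", dict(sorted(items.items())))

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("ElementTally is immutable")

    def __getitem__(self, key: str) -> int:
        return self._counts[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def count(self, element: str) -> int:
        """Atom count for *element*, 0 when absent."""
        return self._counts.get(element, 0)

    def hill(self) -> str:
        """Canonical Hill-order formula string."""
        els = set(self._counts)
        if "C" in els:
            order = ["C"] + (["H"] if "H" in els else []) + sorted(els - {"C", "H"})
        else:
            order = sorted(els)
        return "".join(
            f"{el}{self._counts[el]}" if self._counts[el] != 1 else el for el in order
        )

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementTally):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementTally({self.hill()!r})"


_TOKEN = re.compile(r"[A-Z][a-z]?|\d+|[()]")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        m = _TOKEN.match(text, i)
        if m is None:
            raise FormulaError(f"unexpected character {text[i]!r} at position {i} in {text!r}")
        tokens.append(m.group(0))
        i = m.end()
    return tokens


def _read_count(tokens: list[str], i: int) -> tuple[int, int]:
    if i < len(tokens) and tokens[i].isdigit():
        n = int(tokens[i])
        if n < 1:
            raise MalformedCountError(f"count must be >= 1, got {tokens[i]!r}")
        return n, i + 1
    return 1, i


def _parse_segment(tokens: list[str], i: int, depth: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    while i < len(tokens):
        tok = tokens[i]
        if tok == "(":
            inner, i = _parse_segment(tokens, i + 1, depth + 1)
            if i >= len(tokens) or tokens[i] != ")":
                raise UnbalancedParenthesesError("unmatched '(' in formula")
            mult, i = _read_count(tokens, i + 1)
            for el, c in inner.items():
                counts[el] = counts.get(el, 0) + c * mult
        elif tok == ")":
            if depth == 0:
                raise UnbalancedParenthesesError("unmatched ')' in formula")
            return counts, i
        elif tok.isdigit():
            raise MalformedCountError(f"count {tok!r} is not attached to an element or group")
        else:
            if tok not in ATOMIC_WEIGHTS:
                raise UnknownElementError(f"unknown element symbol {tok!r}")
            mult, i = _read_count(tokens, i + 1)
            counts[tok] = counts.get(tok, 0) + mult
    if depth != 0:
        raise UnbalancedParenthesesError("unmatched '(' in formula")
    return counts, i


def parse_formula(text: str) -> ElementTally:
    """Parse a molecular-formula string into an :class:`ElementTally`.

    Supports nested parentheses with integer multipliers and hydrate
    notation (``CuSO4.5H2O`` or with the middle-dot separator); each
    dot-separated part may carry a leading integer multiplier.

    >>> parse_formula("C6H12O6").hill()
    'C6H12O6'
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    total: dict[str, int] = {}
    for part in re.split(r"[·.*]", text.strip()):
        part = part.strip()
        if not part:
            raise FormulaError(f"empty hydrate part in formula {text!r}")
        mult = 1
        m = re.match(r"(\d+)(.+)", part)
        if m:
            mult = int(m.group(1))
            if mult < 1:
                raise MalformedCountError(f"hydrate multiplier must be >= 1 in {part!r}")
            part = m.group(2)
        tokens = _tokenize(part)
        counts, i = _parse_segment(tokens, 0, 0)
        if i != len(tokens):
            raise UnbalancedParenthesesError(f"unmatched ')' in formula {text!r}")
        for el, c in counts.items():
            total[el] = total.get(el, 0) + mult * c
    return ElementTally(total)


def molar_mass(tally: Mapping[str, int]) -> float:
    """Molar mass (g/mol) of a tally under the bundled atomic-weight table."""
    if len(tally) == 0:
        raise FormulaError("cannot compute molar mass of an empty tally")
    total = 0.0
    for el, c in tally.items():
        try:
            total += ATOMIC_WEIGHTS[el] * c
        except KeyError:
            raise UnknownElementError(f"element {el!r} missing from atomic-weight table") from None
    return total
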