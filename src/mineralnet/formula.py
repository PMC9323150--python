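"""Parsing of ideal (IMA-style) mineral formulas into element sets.

A mineral formula is treated purely as a description of *which* chemical
elements constitute the species, together with per-formula-unit
stoichiometric counts.  Downstream analyses only consume element identity;
stoichiometry is retained for bookkeeping and validation.

Supported syntax
----------------
* element symbols with optional integer or decimal subscripts (``FeCO3``,
  ``Ca0.5``);
* arbitrarily nested groups in parentheses or square brackets with a group
  multiplier (``NaPb2(CO3)2(OH)``, ``K[AlSi3O8]``);
* hydration / adduct segments introduced by a middle dot, bullet, or ASCII
  period, with an optional leading multiplier (``CaSO4·2H2O``);
* comma-separated site occupancies, e.g. ``(Fe,Mg)2SiO4`` — every listed
  element is included, each receiving the group's count;
* Unicode subscript digits and superscript charge annotations, which are
  normalized away before tokenizing (oxidation state never changes element
  identity).

Formulas containing variable subscripts (``Fe1-xS``), placeholder symbols
(``REE``, ``Ln``, ``M``, ``An``), vacancy markers (``□``) or explicit
numeric ranges are *ambiguous*: they parse to an empty element set with
``ambiguous=True`` and are meant to be excluded from analysis rather than
guessed at.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterator

__all__ = [
    "ParsedFormula",
    "FormulaParseError",
    "AmbiguousFormulaError",
    "ELEMENT_SYMBOLS",
    "ATOMIC_NUMBERS",
    "parse_formula",
    "classify_ambiguity",
    "extract_element_set",
]


def _load_periodic_table() -> dict[str, int]:
    with resources.files("mineralnet.data").joinpath("periodic_table.csv").open() as fh:
        return {row["symbol"]: int(row["atomic_number"]) for row in csv.DictReader(fh)}


#: symbol -> atomic number for the 118 IUPAC-recognized elements
ATOMIC_NUMBERS: dict[str, int] = _load_periodic_table()

#: the 118 recognized element symbols
ELEMENT_SYMBOLS: frozenset[str] = frozenset(ATOMIC_NUMBERS)

#: non-element placeholder tokens that mark a formula as ambiguous rather
#: than malformed (rare-earth / lanthanide / generic-metal / actinide sites)
PLACEHOLDER_TOKENS: frozenset[str] = frozenset({"REE", "Ln", "M", "An"})

_VACANCY_CHARS = "□☐"  # white square, ballot box

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_SUPERSCRIPT_CHARS = "⁰¹²³⁴⁵⁶⁷⁸⁹⁺⁻"
_DOT_CHARS = "·•⋅∙"  # middle dot, bullet, dot operator, bullet operator


class FormulaParseError(ValueError):
    """Malformed formula text (unbalanced brackets, unrecognized token)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class AmbiguousFormulaError(ValueError):
    """Raised when an ambiguous formula is used where a definite one is required."""


@dataclass(frozen=True)
class ParsedFormula:
    """A parsed ideal formula: element identity plus stoichiometric counts."""

    source_text: str
    elements: frozenset[str]
    stoichiometry: dict[str, Fraction] = field(compare=False)
    ambiguous: bool = False
    ambiguity_reason: str = ""

    def __post_init__(self) -> None:
        if not self.ambiguous:
            if self.elements != frozenset(self.stoichiometry):
                raise ValueError("element set must equal stoichiometry keys")
            if any(v <= 0 for v in self.stoichiometry.values()):
                raise ValueError("stoichiometric counts must be positive")
        elif not self.ambiguity_reason:
            raise ValueError("ambiguous=True requires an ambiguity_reason")

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def _normalize(text: str) -> str:
    """Normalize Unicode variants: subscripts to digits, drop markup and charges."""
    text = text.strip()
    text = text.translate(_SUBSCRIPT_DIGITS)
    text = text.replace("_", "")  # markdown-style subscript markers, e.g. Fe_2_
    # explicit superscript runs are oxidation states: drop them entirely
    text = re.sub(f"[{_SUPERSCRIPT_CHARS}]+", "", text)
    # caret-delimited charge markup, e.g. Fe^2+^ or Fe^3+
    text = re.sub(r"\^[0-9+−-]*\^?", "", text)
    # unambiguous hydration dots become '*'; ASCII '.' stays and is resolved
    # against decimal subscripts during tokenizing
    for ch in _DOT_CHARS:
        text = text.replace(ch, "*")
    text = re.sub(r"\s+", "", text)
    return text


def _strip_charges(text: str) -> str:
    """Remove inline oxidation-state annotations like ``Fe2+`` or ``(SO4)2−``."""
    return re.sub(r"\d*[+−]", "", text)


_RANGE_RE = re.compile(r"\d\s*[-–]\s*\d")
_VARIABLE_SUB_RE = re.compile(r"(?<![A-Za-z])[xn](?![a-z])")
_HYPHEN_VAR_RE = re.compile(r"[-–][xn](?![a-z])")
_CANDIDATE_TOKEN_RE = re.compile(r"[A-Z][a-z]?")


def classify_ambiguity(
    formula_text: str, occupancy_ambiguous: bool = False
) -> tuple[bool, str]:
    """Decide whether a formula is too ambiguous to yield a definite element set.

    Total on text: never raises.  Comma-separated site occupancies such as
    ``(Fe,Mg)`` are *not* ambiguous by default — all listed elements count
    as constituents — but ``occupancy_ambiguous=True`` treats them as
    ambiguous instead, so a dataset can be analyzed under both readings.
    """
    text = _normalize(formula_text)
    if occupancy_ambiguous and "," in text:
        return True, "site occupancy"
    if any(ch in text for ch in _VACANCY_CHARS):
        return True, "vacancy symbol"
    if "REE" in text:
        return True, "placeholder symbol 'REE'"
    if _HYPHEN_VAR_RE.search(text) or _VARIABLE_SUB_RE.search(text):
        return True, "variable subscript"
    if _RANGE_RE.search(text):
        return True, "explicit range"
    for tok in _CANDIDATE_TOKEN_RE.findall(text):
        if tok in PLACEHOLDER_TOKENS and tok not in ELEMENT_SYMBOLS:
            return True, f"placeholder symbol '{tok}'"
    return False, ""


# --- tokenizer -----------------------------------------------------------

_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}


@dataclass(frozen=True)
class _Token:
    kind: str  # ELEM | NUM | OPEN | CLOSE | DOT | COMMA
    value: str
    pos: int


def _tokenize(text: str) -> Iterator[_Token]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in _OPEN:
            yield _Token("OPEN", ch, i)
            i += 1
        elif ch in _CLOSE:
            yield _Token("CLOSE", ch, i)
            i += 1
        elif ch == ",":
            yield _Token("COMMA", ch, i)
            i += 1
        elif ch == "*":
            yield _Token("DOT", ch, i)
            i += 1
        elif ch == ".":
            # an ASCII period flanked by digits was consumed as a decimal
            # point by the number scanner; any period seen here separates
            # hydration/adduct segments
            yield _Token("DOT", ch, i)
            i += 1
        elif ch.isdigit():
            m = re.match(r"\d+(?:\.\d+)?", text[i:])
            assert m is not None
            yield _Token("NUM", m.group(), i)
            i += len(m.group())
        elif ch.isupper():
            two = text[i : i + 2]
            if len(two) == 2 and two[1].islower() and two in ELEMENT_SYMBOLS:
                yield _Token("ELEM", two, i)
                i += 2
            elif ch in ELEMENT_SYMBOLS:
                yield _Token("ELEM", ch, i)
                i += 1
            else:
                bad = two if len(two) == 2 and two[1].islower() else ch
                raise FormulaParseError(f"unrecognized symbol {bad!r}", i)
        else:
            raise FormulaParseError(f"unexpected character {ch!r}", i)


def _to_fraction(num: str) -> Fraction:
    return Fraction(num) if "." not in num else Fraction(num).limit_denominator(10**6)


class _Parser:
    """Recursive-descent parser over the token stream."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> dict[str, Fraction]:
        stoich = self._segment()
        while (tok := self.peek()) is not None and tok.kind == "DOT":
            self.next()
            _merge(stoich, self._segment())
        if (tok := self.peek()) is not None:
            raise FormulaParseError(f"unexpected {tok.value!r}", tok.pos)
        if not stoich:
            raise FormulaParseError("formula contains no elements", 0)
        return stoich

    def _segment(self) -> dict[str, Fraction]:
        """One dot-separated segment: optional leading multiplier, then terms."""
        mult = Fraction(1)
        if (tok := self.peek()) is not None and tok.kind == "NUM":
            mult = _to_fraction(self.next().value)
        stoich: dict[str, Fraction] = {}
        saw_term = False
        while (tok := self.peek()) is not None and tok.kind in ("ELEM", "OPEN"):
            _merge(stoich, self._term())
            saw_term = True
        if not saw_term:
            tok = self.peek()
            pos = tok.pos if tok is not None else len(self.text)
            raise FormulaParseError("expected an element or group", pos)
        return {el: c * mult for el, c in stoich.items()}

    def _term(self) -> dict[str, Fraction]:
        tok = self.next()
        if tok.kind == "ELEM":
            return {tok.value: self._count()}
        assert tok.kind == "OPEN"
        inner = self._group_body(opener=tok)
        mult = self._count()
        return {el: c * mult for el, c in inner.items()}

    def _group_body(self, opener: _Token) -> dict[str, Fraction]:
        """Contents of a bracketed group; comma-separated units form an
        occupancy list whose members each keep their own counts."""
        units: list[dict[str, Fraction]] = [{}]
        while True:
            tok = self.peek()
            if tok is None:
                raise FormulaParseError(f"unbalanced {opener.value!r}", opener.pos)
            if tok.kind == "CLOSE":
                if tok.value != _OPEN[opener.value]:
                    raise FormulaParseError(
                        f"mismatched bracket {tok.value!r} closing {opener.value!r}", tok.pos
                    )
                self.next()
                break
            if tok.kind == "COMMA":
                self.next()
                units.append({})
                continue
            if tok.kind in ("ELEM", "OPEN"):
                _merge(units[-1], self._term())
                continue
            raise FormulaParseError(f"unexpected {tok.value!r} inside group", tok.pos)
        if any(not u for u in units):
            raise FormulaParseError("empty group", opener.pos)
        combined: dict[str, Fraction] = {}
        for u in units:
            _merge(combined, u)
        return combined

    def _count(self) -> Fraction:
        if (tok := self.peek()) is not None and tok.kind == "NUM":
            return _to_fraction(self.next().value)
        return Fraction(1)


def _merge(into: dict[str, Fraction], other: dict[str, Fraction]) -> None:
    for el, c in other.items():
        into[el] = into.get(el, Fraction(0)) + c


def parse_formula(formula_text: str, occupancy_ambiguous: bool = False) -> ParsedFormula:
    """Parse ideal formula text into a :class:`ParsedFormula`.

    Ambiguity markers (variable subscripts, placeholders, vacancies) do not
    raise; they produce an empty, ``ambiguous=True`` result.  Structural
    errors — unbalanced brackets, symbols that are neither elements nor
    known placeholders — raise :class:`FormulaParseError` naming the
    offending position.  ``occupancy_ambiguous`` is forwarded to
    :func:`classify_ambiguity`.
    """
    if not formula_text or not formula_text.strip():
        raise FormulaParseError("empty formula text")
    ambiguous, reason = classify_ambiguity(formula_text, occupancy_ambiguous)
    if ambiguous:
        return ParsedFormula(formula_text, frozenset(), {}, ambiguous=True, ambiguity_reason=reason)
    text = _strip_charges(_normalize(formula_text))
    stoich = _Parser(text).parse()
    return ParsedFormula(formula_text, frozenset(stoich), stoich)


def extract_element_set(parsed: ParsedFormula) -> frozenset[str]:
    """Element identity of a parsed formula; refuses ambiguous input."""
    if parsed.ambiguous:
        raise AmbiguousFormulaError(
            f"formula {parsed.source_text!r} is ambiguous ({parsed.ambiguity_reason}); "
            "exclude it from analysis"
        )
    return parsed.elements
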