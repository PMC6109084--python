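"""A small atom-selection grammar.

Grammar (case-insensitive keywords, whitespace-separated tokens)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := not_expr ( "and" not_expr )*
    not_expr := "not" not_expr | primary
    primary  := "(" expr ")"
              | "resid"   (INT | INT-INT)+
              | "resname" WORD+
              | "name"    WORD+
              | "chain"   WORD+
              | "backbone"
              | "all"
              | "within" FLOAT "of" primary

``backbone`` selects atoms named N, CA, C or O.  ``within r of X`` selects
atoms whose distance to any atom of X is <= r (X itself is included, since
its atoms are at distance zero).  Parse errors report the 1-based column of
the offending token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomIndexSet, Structure

__all__ = ["SelectionError", "select"]

_BACKBONE_NAMES = {"N", "CA", "C", "O"}
_KEYWORDS = {"and", "or", "not", "resid", "resname", "name", "chain",
             "backbone", "all", "within", "of", "(", ")"}


class SelectionError(ValueError):
    """Selection grammar error; carries the 1-based column position."""

    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass
class _Token:
    text: str
    column: int  # 1-based


def _tokenize(expression: str) -> List[_Token]:
    tokens = []
    for m in re.finditer(r"\(|\)|[^\s()]+", expression):
        tokens.append(_Token(m.group(0), m.start() + 1))
    return tokens


class _Parser:
    """Recursive-descent parser evaluating directly to boolean masks."""

    def __init__(self, tokens: List[_Token], structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = structure
        self._tree: Optional[cKDTree] = None

    # -- token helpers -------------------------------------------------
    def _peek(self) -> Optional[_Token]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self, expect: Optional[str] = None) -> _Token:
        tok = self._peek()
        if tok is None:
            col = self.tokens[-1].column + len(self.tokens[-1].text) if self.tokens else 1
            raise SelectionError(f"unexpected end of expression"
                                 + (f", expected {expect!r}" if expect else ""), col)
        if expect is not None and tok.text.lower() != expect:
            raise SelectionError(f"expected {expect!r}, found {tok.text!r}", tok.column)
        self.pos += 1
        return tok

    # -- grammar -------------------------------------------------------
    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        tok = self._peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok.text!r}", tok.column)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while (tok := self._peek()) is not None and tok.text.lower() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while (tok := self._peek()) is not None and tok.text.lower() == "and":
            self._next()
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        tok = self._peek()
        if tok is not None and tok.text.lower() == "not":
            self._next()
            return ~self._not_expr()
        return self._primary()

    def _values(self, clause: str) -> List[_Token]:
        vals = []
        while (tok := self._peek()) is not None and tok.text.lower() not in _KEYWORDS:
            vals.append(self._next())
        if not vals:
            col = self.tokens[self.pos - 1].column
            raise SelectionError(f"{clause!r} requires at least one value", col)
        return vals

    def _primary(self) -> np.ndarray:
        tok = self._next()
        kw = tok.text.lower()
        n = self.s.n_atoms
        if kw == "(":
            mask = self._or_expr()
            self._next(expect=")")
            return mask
        if kw == "all":
            return np.ones(n, dtype=bool)
        if kw == "backbone":
            return np.isin(np.array([str(x).upper() for x in self.s.names]),
                           list(_BACKBONE_NAMES))
        if kw == "resid":
            mask = np.zeros(n, dtype=bool)
            for val in self._values("resid"):
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", val.text)
                if not m:
                    raise SelectionError(f"bad residue id or range {val.text!r}",
                                         val.column)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= (self.s.resids >= lo) & (self.s.resids <= hi)
            return mask
        if kw in ("resname", "name", "chain"):
            attr = {"resname": "resnames", "name": "names", "chain": "chains"}[kw]
            wanted = {v.text.upper() for v in self._values(kw)}
            values = np.array([str(x).upper() for x in getattr(self.s, attr)])
            return np.isin(values, list(wanted))
        if kw == "within":
            rtok = self._next()
            try:
                cutoff = float(rtok.text)
            except ValueError:
                raise SelectionError(f"expected a distance, found {rtok.text!r}",
                                     rtok.column) from None
            if cutoff < 0:
                raise SelectionError("distance must be non-negative", rtok.column)
            self._next(expect="of")
            ref_mask = self._primary()
            if not ref_mask.any():
                return np.zeros(n, dtype=bool)
            tree = cKDTree(self.s.coords[ref_mask])
            d, _ = tree.query(self.s.coords, k=1)
            return d <= cutoff
        raise SelectionError(f"unknown token {tok.text!r}", tok.column)


def select(structure: Structure, expression: str) -> AtomIndexSet:
    """Evaluate a selection expression on a structure.

    Returns an :class:`AtomIndexSet` of 0-based atom positions in structure
    order.  Deterministic; an empty result is valid.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty expression", 1)
    mask = _Parser(tokens, structure).parse()
    return AtomIndexSet(np.flatnonzero(mask), selection_text=expression)
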