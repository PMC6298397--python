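"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``AND`` joins subunits of an enzyme complex (all required), ``OR`` joins
isozymes (any one suffices).  A reaction with an empty rule has no gene
association and survives every knockout.

Grammar (case-insensitive keywords, ``AND`` binds tighter than ``OR``)::

    expr    := term   (OR  term)*
    term    := factor (AND factor)*
    factor  := GENE | '(' expr ')'

Gene identifiers are any run of non-whitespace, non-parenthesis characters
that is not one of the keywords.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Union


class GprParseError(ValueError):
    """Malformed GPR expression; carries the offending token position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GeneRef:
    gene: str

    def evaluate(self, knocked_out: AbstractSet[str]) -> bool:
        return self.gene not in knocked_out

    @property
    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple[Union["BoolOp", GeneRef], ...]

    def evaluate(self, knocked_out: AbstractSet[str]) -> bool:
        if self.op == "and":
            return all(c.evaluate(knocked_out) for c in self.children)
        return any(c.evaluate(knocked_out) for c in self.children)

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes
        return out

    def to_string(self) -> str:
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, BoolOp) and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


GprNode = Union[BoolOp, GeneRef]


@dataclass(frozen=True)
class GprRule:
    """A parsed GPR expression tree; ``root is None`` means no association."""

    root: GprNode | None = None

    @classmethod
    def from_string(cls, text: str | None) -> "GprRule":
        if text is None or not text.strip():
            return cls(None)
        return cls(_Parser(text).parse())

    @property
    def genes(self) -> frozenset[str]:
        return self.root.genes if self.root is not None else frozenset()

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """True iff the reaction remains catalysed after removing *knocked_out*."""
        if self.root is None:
            return True
        ko = knocked_out if isinstance(knocked_out, (set, frozenset)) else set(knocked_out)
        return self.root.evaluate(ko)

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __bool__(self) -> bool:
        return self.root is not None


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]
        self.pos = 0

    def parse(self) -> GprNode:
        node = self._expr()
        if self.pos < len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise GprParseError(f"unexpected token {tok!r}", at)
        return node

    def _peek(self) -> str | None:
        if self.pos < len(self.tokens):
            return self.tokens[self.pos][0]
        return None

    def _expr(self) -> GprNode:
        terms = [self._term()]
        while (tok := self._peek()) is not None and tok.lower() == "or":
            self.pos += 1
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else BoolOp("or", tuple(terms))

    def _term(self) -> GprNode:
        factors = [self._factor()]
        while (tok := self._peek()) is not None and tok.lower() == "and":
            self.pos += 1
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else BoolOp("and", tuple(factors))

    def _factor(self) -> GprNode:
        if self.pos >= len(self.tokens):
            raise GprParseError("unexpected end of expression", len(self.text))
        tok, at = self.tokens[self.pos]
        if tok == "(":
            self.pos += 1
            node = self._expr()
            if self._peek() != ")":
                raise GprParseError("unbalanced parenthesis", at)
            self.pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r}", at)
        self.pos += 1
        return GeneRef(tok)


def evaluate_gpr(rule: GprRule | str | None, knocked_out: Iterable[str] = ()) -> bool:
    """Evaluate a GPR rule under a gene-knockout set.

    Accepts a parsed :class:`GprRule` or a raw rule string.  An empty rule is
    always active.
    """
    if not isinstance(rule, GprRule):
        rule = GprRule.from_string(rule)
    return rule.evaluate(knocked_out)
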