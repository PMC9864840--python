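"""Gene-protein-reaction (GPR) expressions.

A GPR is a boolean expression over gene identifiers in which ``and``
denotes subunits of one enzyme complex and ``or`` denotes isozymes.
The expression tree uses n-ary AND/OR nodes: chains of the same operator
are flattened, and ``and`` binds tighter than ``or``, so
``a and b or c`` parses as ``OR(AND(a, b), c)``.

The tree is the substrate of two model transformations: isozyme
splitting (one reaction per top-level OR child) and complex molecular
weight computation (sum over AND members).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .exceptions import GPRSyntaxError

__all__ = ["Gene", "And", "Or", "GPR", "parse_gpr"]


@dataclass(frozen=True)
class Gene:
    name: str

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise GPRSyntaxError("AND node requires at least 2 children")

    def to_string(self) -> str:
        return " and ".join(
            f"({c.to_string()})" if isinstance(c, Or) else c.to_string()
            for c in self.children
        )


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise GPRSyntaxError("OR node requires at least 2 children")

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


Node = Gene | And | Or

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser: expr := term ('or' term)*; term := factor ('and' factor)*."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of GPR expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRSyntaxError(f"unexpected token {tok[0]!r}", tok[1])
        return node

    def expr(self) -> Node:
        children = [self.term()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "or":
                break
            self.next()
            children.append(self.term())
        return children[0] if len(children) == 1 else Or(tuple(_flatten(children, Or)))

    def term(self) -> Node:
        children = [self.factor()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "and":
                break
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else And(tuple(_flatten(children, And)))

    def factor(self) -> Node:
        tok, pos = self.next()
        if tok == "(":
            node = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GPRSyntaxError("unbalanced parentheses", pos)
            self.next()
            return node
        if tok == ")":
            raise GPRSyntaxError("unbalanced parentheses", pos)
        if tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"dangling operator {tok!r}", pos)
        return Gene(tok)


def _flatten(children: list[Node], cls: type) -> list[Node]:
    out: list[Node] = []
    for c in children:
        if isinstance(c, cls):
            out.extend(c.children)
        else:
            out.append(c)
    return out


@dataclass(frozen=True)
class GPR:
    """A parsed GPR expression; ``root`` is None for spontaneous reactions."""

    root: Node | None = None

    @classmethod
    def from_string(cls, text: str) -> "GPR":
        text = text.strip()
        if not text:
            return cls(None)
        return cls(_Parser(text).parse())

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def genes(self) -> frozenset[str]:
        def walk(node: Node):
            if isinstance(node, Gene):
                yield node.name
            else:
                for c in node.children:
                    yield from walk(c)

        return frozenset(walk(self.root)) if self.root is not None else frozenset()

    def evaluate(self, active: set[str]) -> bool:
        """Boolean evaluation: is the reaction catalysable given active genes?"""

        def ev(node: Node) -> bool:
            if isinstance(node, Gene):
                return node.name in active
            if isinstance(node, And):
                return all(ev(c) for c in node.children)
            return any(ev(c) for c in node.children)

        return True if self.root is None else ev(self.root)

    def contains_or(self) -> bool:
        def walk(node: Node) -> bool:
            if isinstance(node, Or):
                return True
            if isinstance(node, Gene):
                return False
            return any(walk(c) for c in node.children)

        return False if self.root is None else walk(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str) -> GPR:
    """Parse GPR text into an expression tree.

    ``and`` binds tighter than ``or``; same-operator chains flatten into
    one n-ary node; the empty string parses to an empty (spontaneous)
    expression. Raises :class:`GPRSyntaxError` with a position on
    unbalanced parentheses or dangling operators.
    """
    return GPR.from_string(text)
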