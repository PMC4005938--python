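"""Parser and evaluator for the LEMS arithmetic/boolean expression language.

LEMS expressions appear in time derivatives, derived variables, state
assignments and condition tests.  Because the host format is XML, the
language uses Fortran-style comparison operators (``.gt.``, ``.lt.``,
``.geq.``, ``.leq.``, ``.eq.``, ``.neq.``) instead of ``>`` / ``<``; the
bare keyword spellings (``v gt thresh``) are also accepted on input, and the
dotted form is the canonical output.  Boolean connectives are ``.and.``,
``.or.`` and ``.not.``.

Operator precedence, loosest to tightest::

    .or.  <  .and.  <  .not.  <  comparisons  <  + -  <  * /  <  unary -  <  ^

``^`` is right-associative (``2^3^2 == 512``) and binds tighter than unary
minus (``-2^2 == -4``).

The evaluator is a plain AST walker and is the semantic reference for the
language.  :func:`compile_expr` produces a fast callable for the simulator's
inner loop; its output is cross-checked against :func:`eval_expr` in tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import EvalError, ParseError

__all__ = [
    "parse_expr",
    "eval_expr",
    "free_variables",
    "to_string",
    "compile_expr",
    "Num",
    "Var",
    "Bin",
    "Neg",
    "Call",
    "Cmp",
    "Bool",
    "Not",
]

COMPARISONS = ("gt", "lt", "geq", "leq", "eq", "neq")
BOOL_OPS = ("and", "or")

FUNCTIONS = {
    "exp": math.exp,
    "ln": math.log,
    "log": math.log,  # LEMS 'log' is the natural log, same as 'ln'
    "sqrt": math.sqrt,
    "abs": abs,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
}


# --------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Bin:
    op: str  # + - * / ^
    left: object
    right: object


@dataclass(frozen=True)
class Neg:
    operand: object


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple


@dataclass(frozen=True)
class Cmp:
    op: str  # gt lt geq leq eq neq
    left: object
    right: object


@dataclass(frozen=True)
class Bool:
    op: str  # and or
    left: object
    right: object


@dataclass(frozen=True)
class Not:
    operand: object


# --------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<dotop>\.(?:gt|lt|geq|leq|eq|neq|and|or|not)\.)
  | (?P<number>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z_0-9]*)
  | (?P<op>[-+*/^(),])
    """,
    re.VERBOSE,
)


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise ParseError(f"unexpected character {text[pos]!r} at position {pos}")
        pos = match.end()
        if match.lastgroup == "ws":
            continue
        kind = match.lastgroup
        value = match.group()
        if kind == "dotop":
            value = value.strip(".")
        tokens.append((kind, value, match.start()))
    tokens.append(("eof", "", len(text)))
    return tokens


# --------------------------------------------------------------------------
# Parser (recursive descent)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    def peek(self):
        return self.tokens[self.index]

    def advance(self):
        token = self.tokens[self.index]
        self.index += 1
        return token

    def error(self, message: str):
        kind, value, pos = self.peek()
        raise ParseError(f"{message} at position {pos} in {self.text!r}")

    def at_keyword(self, names) -> str | None:
        """Operator keyword at the cursor, dotted or bare-word form."""
        kind, value, _ = self.peek()
        if kind == "dotop" and value in names:
            return value
        if kind == "ident" and value in names:
            return value
        return None

    def parse(self):
        expr = self.parse_or()
        if self.peek()[0] != "eof":
            self.error("trailing input")
        return expr

    def parse_or(self):
        left = self.parse_and()
        while self.at_keyword(("or",)):
            self.advance()
            left = Bool("or", left, self.parse_and())
        return left

    def parse_and(self):
        left = self.parse_not()
        while self.at_keyword(("and",)):
            self.advance()
            left = Bool("and", left, self.parse_not())
        return left

    def parse_not(self):
        if self.at_keyword(("not",)):
            self.advance()
            return Not(self.parse_not())
        return self.parse_comparison()

    def parse_comparison(self):
        left = self.parse_additive()
        op = self.at_keyword(COMPARISONS)
        if op is not None:
            self.advance()
            return Cmp(op, left, self.parse_additive())
        return left

    def parse_additive(self):
        left = self.parse_multiplicative()
        while self.peek()[:2] in (("op", "+"), ("op", "-")):
            op = self.advance()[1]
            left = Bin(op, left, self.parse_multiplicative())
        return left

    def parse_multiplicative(self):
        left = self.parse_unary()
        while self.peek()[:2] in (("op", "*"), ("op", "/")):
            op = self.advance()[1]
            left = Bin(op, left, self.parse_unary())
        return left

    def parse_unary(self):
        if self.peek()[:2] == ("op", "-"):
            self.advance()
            return Neg(self.parse_unary())
        if self.peek()[:2] == ("op", "+"):
            self.advance()
            return self.parse_unary()
        return self.parse_power()

    def parse_power(self):
        base = self.parse_atom()
        if self.peek()[:2] == ("op", "^"):
            self.advance()
            # right-associative; exponent may carry a unary minus (2^-3)
            return Bin("^", base, self.parse_unary())
        return base

    def parse_atom(self):
        kind, value, _ = self.peek()
        if kind == "number":
            self.advance()
            return Num(float(value))
        if kind == "ident":
            self.advance()
            if self.peek()[:2] == ("op", "("):
                self.advance()
                args = [self.parse_or()]
                while self.peek()[:2] == ("op", ","):
                    self.advance()
                    args.append(self.parse_or())
                if self.peek()[:2] != ("op", ")"):
                    self.error("expected ')'")
                self.advance()
                if value not in FUNCTIONS:
                    raise ParseError(f"unknown function {value!r}")
                return Call(value, tuple(args))
            return Var(value)
        if kind == "op" and value == "(":
            self.advance()
            expr = self.parse_or()
            if self.peek()[:2] != ("op", ")"):
                self.error("unbalanced parenthesis")
            self.advance()
            return expr
        self.error("expected a value")


def parse_expr(text: str):
    """Parse LEMS expression text into an AST."""
    if not text or not text.strip():
        raise ParseError("empty expression")
    return _Parser(text).parse()


# --------------------------------------------------------------------------
# Evaluation

_ARITH = {
    "+": lambda a, b: a + b,
    "-": lambda a, b: a - b,
    "*": lambda a, b: a * b,
    "/": lambda a, b: a / b,
    "^": lambda a, b: a ** b,
}

_CMP = {
    "gt": lambda a, b: a > b,
    "lt": lambda a, b: a < b,
    "geq": lambda a, b: a >= b,
    "leq": lambda a, b: a <= b,
    "eq": lambda a, b: a == b,
    "neq": lambda a, b: a != b,
}


def eval_expr(expr, env):
    """Evaluate an AST under ``env`` (identifier -> SI real).

    Comparisons and boolean connectives return ``bool``; everything else
    returns ``float``.  ``env`` is never mutated.  Unbound identifiers raise
    :class:`~neurolems.errors.EvalError` naming the identifier.
    """
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Var):
        try:
            return env[expr.name]
        except KeyError:
            raise EvalError(f"unbound identifier {expr.name!r}") from None
    if isinstance(expr, Bin):
        return _ARITH[expr.op](eval_expr(expr.left, env), eval_expr(expr.right, env))
    if isinstance(expr, Neg):
        return -eval_expr(expr.operand, env)
    if isinstance(expr, Call):
        return FUNCTIONS[expr.func](*(eval_expr(a, env) for a in expr.args))
    if isinstance(expr, Cmp):
        return _CMP[expr.op](eval_expr(expr.left, env), eval_expr(expr.right, env))
    if isinstance(expr, Bool):
        left = eval_expr(expr.left, env)
        if expr.op == "and":
            return bool(left) and bool(eval_expr(expr.right, env))
        return bool(left) or bool(eval_expr(expr.right, env))
    if isinstance(expr, Not):
        return not eval_expr(expr.operand, env)
    raise TypeError(f"not an expression node: {expr!r}")


def free_variables(expr) -> set:
    """Identifiers appearing in ``expr``, excluding function names."""
    out: set[str] = set()
    _collect(expr, out)
    return out


def _collect(expr, out):
    if isinstance(expr, Var):
        out.add(expr.name)
    elif isinstance(expr, (Bin, Cmp, Bool)):
        _collect(expr.left, out)
        _collect(expr.right, out)
    elif isinstance(expr, (Neg, Not)):
        _collect(expr.operand, out)
    elif isinstance(expr, Call):
        for arg in expr.args:
            _collect(arg, out)


# --------------------------------------------------------------------------
# Printing / compilation


def to_string(expr) -> str:
    """Canonical, fully parenthesized text form; ``parse(to_string(e)) == e``."""
    if isinstance(expr, Num):
        text = repr(expr.value)
        return text[:-2] if text.endswith(".0") else text
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Bin):
        return f"({to_string(expr.left)} {expr.op} {to_string(expr.right)})"
    if isinstance(expr, Neg):
        return f"(- {to_string(expr.operand)})"
    if isinstance(expr, Call):
        return f"{expr.func}({', '.join(to_string(a) for a in expr.args)})"
    if isinstance(expr, Cmp):
        return f"({to_string(expr.left)} .{expr.op}. {to_string(expr.right)})"
    if isinstance(expr, Bool):
        return f"({to_string(expr.left)} .{expr.op}. {to_string(expr.right)})"
    if isinstance(expr, Not):
        return f"(.not. {to_string(expr.operand)})"
    raise TypeError(f"not an expression node: {expr!r}")


_PY_CMP = {"gt": ">", "lt": "<", "geq": ">=", "leq": "<=", "eq": "==", "neq": "!="}


def _to_python(expr) -> str:
    if isinstance(expr, Num):
        return repr(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Bin):
        op = "**" if expr.op == "^" else expr.op
        return f"({_to_python(expr.left)} {op} {_to_python(expr.right)})"
    if isinstance(expr, Neg):
        return f"(-{_to_python(expr.operand)})"
    if isinstance(expr, Call):
        return f"{expr.func}({', '.join(_to_python(a) for a in expr.args)})"
    if isinstance(expr, Cmp):
        return f"({_to_python(expr.left)} {_PY_CMP[expr.op]} {_to_python(expr.right)})"
    if isinstance(expr, Bool):
        return f"({_to_python(expr.left)} {expr.op} {_to_python(expr.right)})"
    if isinstance(expr, Not):
        return f"(not {_to_python(expr.operand)})"
    raise TypeError(f"not an expression node: {expr!r}")


_COMPILE_GLOBALS = {"__builtins__": {}, **FUNCTIONS}


def compile_expr(expr):
    """Compile an AST to a fast ``fn(env) -> value`` callable.

    Used by the simulator's inner loop.  Identical semantics to
    :func:`eval_expr` except that unbound identifiers surface as
    :class:`~neurolems.errors.EvalError` only when the callable runs.
    """
    code = compile(_to_python(expr), "<lems-expr>", "eval")

    def fn(env, _code=code):
        try:
            return eval(_code, _COMPILE_GLOBALS, env)
        except NameError as exc:  # pragma: no cover - defensive
            raise EvalError(str(exc)) from None

    return fn
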