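"""Safe evaluation of algebraic expressions used by equation nodes.

Equation nodes define a molecule's steady-state level as an arbitrary
algebraic function of other concentrations (e.g. a weighted summation of
several inputs).  The grammar is a strict whitelist -- numeric literals,
names, ``+ - * /``, ``**``, unary minus, parentheses and the functions
``exp``, ``log``, ``pow``, ``min``, ``max`` -- parsed through the host
AST but never executed as host code.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field


class ExpressionError(ValueError):
    """Raised for syntax errors, unknown names or disallowed constructs."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class EvaluationError(ArithmeticError):
    """Raised when evaluation hits a numeric domain error (e.g. 1/0)."""


_FUNCTIONS = {
    "exp": math.exp,
    "log": math.log,
    "pow": math.pow,
    "min": min,
    "max": max,
}

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
    ast.Pow: lambda a, b: a**b,
}


@dataclass(frozen=True)
class Expr:
    """A validated, immutable expression tree.

    ``names`` is the set of identifiers the expression reads; evaluation
    is a pure function of an environment supplying those names.
    """

    text: str
    tree: ast.expression = field(repr=False, compare=False)
    names: frozenset[str] = frozenset()


def parse(expr_text: str, namespace: set[str] | frozenset[str]) -> Expr:
    """Parse ``expr_text`` against the whitelist grammar.

    Parameters
    ----------
    expr_text:
        The expression source, e.g. ``"0.5*a + 2*b"``.
    namespace:
        Names that may appear in the expression (the model's molecules).

    Raises
    ------
    ExpressionError
        On malformed syntax, identifiers outside ``namespace``, or any
        construct outside the whitelist.
    """
    try:
        tree = ast.parse(expr_text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"syntax error in {expr_text!r}: {exc.msg}",
                              exc.offset) from None
    names: set[str] = set()
    _check(tree.body, expr_text, set(namespace), names)
    return Expr(text=expr_text, tree=tree, names=frozenset(names))


def _check(node: ast.AST, text: str, namespace: set[str], names: set[str]) -> None:
    pos = getattr(node, "col_offset", None)
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)) or isinstance(node.value, bool):
            raise ExpressionError(
                f"literal {node.value!r} is not numeric in {text!r}", pos)
    elif isinstance(node, ast.Name):
        if node.id not in namespace:
            raise ExpressionError(
                f"unknown identifier {node.id!r} in {text!r}", pos)
        names.add(node.id)
    elif isinstance(node, ast.BinOp):
        if type(node.op) not in _BINOPS:
            raise ExpressionError(
                f"operator {type(node.op).__name__} not allowed in {text!r}", pos)
        _check(node.left, text, namespace, names)
        _check(node.right, text, namespace, names)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, (ast.USub, ast.UAdd)):
            raise ExpressionError(
                f"unary operator {type(node.op).__name__} not allowed in {text!r}", pos)
        _check(node.operand, text, namespace, names)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
            raise ExpressionError(f"disallowed function call in {text!r}", pos)
        if node.keywords:
            raise ExpressionError(f"keyword arguments not allowed in {text!r}", pos)
        for arg in node.args:
            _check(arg, text, namespace, names)
    else:
        raise ExpressionError(
            f"disallowed construct {type(node).__name__} in {text!r}", pos)


def evaluate(expr: Expr, env: dict[str, float]) -> float:
    """Evaluate a parsed expression under ``env`` (IEEE-754 doubles)."""
    missing = expr.names - env.keys()
    if missing:
        raise EvaluationError(
            f"environment missing names {sorted(missing)} for {expr.text!r}")
    try:
        value = _eval(expr.tree.body, env)
    except (ZeroDivisionError, ValueError, OverflowError) as exc:
        raise EvaluationError(f"cannot evaluate {expr.text!r}: {exc}") from None
    return float(value)


def _eval(node: ast.AST, env: dict[str, float]) -> float:
    if isinstance(node, ast.Constant):
        return float(node.value)
    if isinstance(node, ast.Name):
        return float(env[node.id])
    if isinstance(node, ast.BinOp):
        return _BINOPS[type(node.op)](_eval(node.left, env), _eval(node.right, env))
    if isinstance(node, ast.UnaryOp):
        v = _eval(node.operand, env)
        return -v if isinstance(node.op, ast.USub) else v
    if isinstance(node, ast.Call):
        fn = _FUNCTIONS[node.func.id]  # type: ignore[union-attr]
        return float(fn(*[_eval(a, env) for a in node.args]))
    raise AssertionError(f"unreachable node {type(node).__name__}")
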