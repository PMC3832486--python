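"""Restricted arithmetic expression interpreter for rate laws.

Rate-law expressions are parsed into a whitelisted Python AST and compiled
once; evaluation binds species copy numbers and model parameters by name.
Only arithmetic (+ - * / ^), parentheses, numeric literals, identifiers and
the functions min/max/exp/log are admitted — no attribute access, no
subscripts, no general code execution.
"""

from __future__ import annotations

import ast
import math
from typing import Iterable, Mapping

__all__ = ["ExpressionError", "RateExpression"]

_ALLOWED_FUNCS = {"min": min, "max": max, "exp": math.exp, "log": math.log}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)


class ExpressionError(ValueError):
    """Raised for syntax errors, disallowed constructs, or evaluation failures."""


def _validate(node: ast.AST, names: set[str]) -> None:
    if isinstance(node, ast.Expression):
        _validate(node.body, names)
    elif isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(
                f"operator {type(node.op).__name__} not allowed in rate expressions"
            )
        _validate(node.left, names)
        _validate(node.right, names)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARY):
            raise ExpressionError(
                f"operator {type(node.op).__name__} not allowed in rate expressions"
            )
        _validate(node.operand, names)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"literal {node.value!r} not allowed")
    elif isinstance(node, ast.Name):
        names.add(node.id)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
            raise ExpressionError("only min/max/exp/log function calls are allowed")
        if node.keywords:
            raise ExpressionError("keyword arguments not allowed")
        for arg in node.args:
            _validate(arg, names)
    else:
        raise ExpressionError(f"construct {type(node).__name__} not allowed")


class RateExpression:
    """A compiled, safe arithmetic expression over species and parameter names.

    ``^`` is accepted as the power operator (translated to ``**``).
    """

    def __init__(self, text: str):
        self.text = text.strip()
        if not self.text:
            raise ExpressionError("empty expression")
        py_text = self.text.replace("^", "**")
        try:
            tree = ast.parse(py_text, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(f"invalid expression {text!r}: {exc.msg}") from exc
        names: set[str] = set()
        _validate(tree, names)
        self.variables: frozenset[str] = frozenset(names - set(_ALLOWED_FUNCS))
        self._code = compile(tree, "<rate-expression>", "eval")

    def check_resolvable(self, known: Iterable[str]) -> None:
        """Raise if the expression references a name not in *known*."""
        missing = self.variables - set(known)
        if missing:
            raise ExpressionError(
                f"undefined identifier {sorted(missing)[0]!r} in rate expression {self.text!r}"
            )

    def __call__(self, env: Mapping[str, float]) -> float:
        try:
            return float(eval(self._code, {"__builtins__": {}, **_ALLOWED_FUNCS}, env))
        except ZeroDivisionError as exc:
            raise ExpressionError(
                f"division by zero evaluating {self.text!r}"
            ) from exc
        except NameError as exc:
            raise ExpressionError(
                f"unresolved name evaluating {self.text!r}: {exc}"
            ) from exc

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RateExpression({self.text!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, RateExpression) and self.text == other.text

    def __hash__(self) -> int:
        return hash(self.text)
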