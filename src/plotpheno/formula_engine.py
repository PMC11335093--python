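"""Arithmetic trait-formula parser, evaluator and preset index registry.

The grammar covers numeric literals, variables, unary minus, ``+ - * /``
and right-associative ``^`` (``**`` accepted as alias), parentheses and
``sqrt(x)``. Evaluation is element-wise over numpy arrays or scalars with
missing-value semantics: division by zero, negative sqrt arguments and NaN
inputs all evaluate to NaN.

The registry ships the preset vegetation indices — 10 usable on both RGB
and multispectral imagery and 11 requiring red-edge/near-infrared bands —
plus a documented ``MSAVI_std`` variant carrying the conventional ÷2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureFormula",
    "FormulaRegistry",
    "FormulaSyntaxError",
    "evaluate_formula",
    "get_preset",
    "parse_formula",
    "registry",
]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>\*\*|[-+*/^()]))"
)

_FUNCTIONS = {"sqrt"}


class FormulaSyntaxError(ValueError):
    """Malformed formula expression, carrying the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# AST nodes are plain tuples: ("num", v) | ("var", name) | ("neg", t)
# | ("add"|"sub"|"mul"|"div"|"pow", left, right) | ("call", fname, arg)

_BINOPS = {"+": "add", "-": "sub", "*": "mul", "/": "div", "^": "pow", "**": "pow"}


def _tokenize(expression: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        match = _TOKEN_RE.match(expression, pos)
        if match is None:
            rest = expression[pos:].lstrip()
            if not rest:
                break
            raise FormulaSyntaxError(f"unexpected character {rest[0]!r}",
                                     len(expression) - len(rest))
        kind = match.lastgroup
        tokens.append((kind, match.group(kind), match.start(kind)))
        pos = match.end()
    return tokens


class _Parser:
    def __init__(self, expression: str):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.index = 0

    def peek(self):
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def next(self):
        token = self.peek()
        if token is not None:
            self.index += 1
        return token

    def expect_op(self, op: str):
        token = self.next()
        if token is None or token[0] != "op" or token[1] != op:
            pos = token[2] if token else len(self.expression)
            raise FormulaSyntaxError(f"expected {op!r}", pos)

    def parse(self):
        tree = self.expr()
        leftover = self.peek()
        if leftover is not None:
            raise FormulaSyntaxError(f"unexpected token {leftover[1]!r}", leftover[2])
        return tree

    def expr(self):
        tree = self.term()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "+-":
            self.next()
            tree = (_BINOPS[tok[1]], tree, self.term())
        return tree

    def term(self):
        tree = self.unary()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "*/":
            self.next()
            tree = (_BINOPS[tok[1]], tree, self.unary())
        return tree

    def unary(self):
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] == "-":
            self.next()
            return ("neg", self.unary())
        return self.power()

    def power(self):
        base = self.atom()
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in ("^", "**"):
            self.next()
            return ("pow", base, self.unary())  # right-associative
        return base

    def atom(self):
        token = self.next()
        if token is None:
            raise FormulaSyntaxError("unexpected end of expression",
                                     len(self.expression))
        kind, text, pos = token
        if kind == "num":
            return ("num", float(text))
        if kind == "name":
            nxt = self.peek()
            if nxt and nxt[0] == "op" and nxt[1] == "(":
                if text not in _FUNCTIONS:
                    raise FormulaSyntaxError(f"unknown function {text!r}", pos)
                self.next()
                arg = self.expr()
                self.expect_op(")")
                return ("call", text, arg)
            return ("var", text)
        if kind == "op" and text == "(":
            tree = self.expr()
            self.expect_op(")")
            return tree
        raise FormulaSyntaxError(f"unexpected token {text!r}", pos)


def _collect_variables(tree, out: set[str]) -> None:
    tag = tree[0]
    if tag == "var":
        out.add(tree[1])
    elif tag == "neg":
        _collect_variables(tree[1], out)
    elif tag == "call":
        _collect_variables(tree[2], out)
    elif tag in ("add", "sub", "mul", "div", "pow"):
        _collect_variables(tree[1], out)
        _collect_variables(tree[2], out)


def tree_to_expression(tree) -> str:
    """Serialize an AST back to text; re-parsing yields an equal tree."""
    tag = tree[0]
    if tag == "num":
        value = tree[1]
        return repr(int(value)) if value == int(value) else repr(value)
    if tag == "var":
        return tree[1]
    if tag == "neg":
        return f"(-{tree_to_expression(tree[1])})"
    if tag == "call":
        return f"{tree[1]}({tree_to_expression(tree[2])})"
    symbol = {"add": "+", "sub": "-", "mul": "*", "div": "/", "pow": "^"}[tag]
    return f"({tree_to_expression(tree[1])}{symbol}{tree_to_expression(tree[2])})"


@dataclass(frozen=True)
class FeatureFormula:
    """A named, parsed trait formula."""

    name: str
    expression: str
    tree: tuple = field(compare=False)
    variables: frozenset = field(compare=False)

    def __str__(self) -> str:
        return f"{self.name} = {self.expression}"


def parse_formula(name: str, expression: str) -> FeatureFormula:
    """Parse an expression into a :class:`FeatureFormula`.

    Unknown variables are not rejected here — they surface at evaluation
    (bind) time, so formulas may reference earlier-defined trait names.
    """
    if not expression or not expression.strip():
        raise FormulaSyntaxError("empty expression", 0)
    tree = _Parser(expression).parse()
    variables: set[str] = set()
    _collect_variables(tree, variables)
    return FeatureFormula(name, expression, tree, frozenset(variables))


def _eval(tree, bindings):
    tag = tree[0]
    if tag == "num":
        return tree[1]
    if tag == "var":
        return bindings[tree[1]]
    if tag == "neg":
        return -_eval(tree[1], bindings)
    if tag == "call":  # only sqrt
        arg = np.asarray(_eval(tree[2], bindings), dtype=float)
        with np.errstate(invalid="ignore"):
            return np.sqrt(arg)
    left = _eval(tree[1], bindings)
    right = _eval(tree[2], bindings)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if tag == "add":
            return np.add(left, right, dtype=float)
        if tag == "sub":
            return np.subtract(left, right, dtype=float)
        if tag == "mul":
            return np.multiply(left, right, dtype=float)
        if tag == "div":
            return np.divide(left, right, dtype=float)
        return np.power(np.asarray(left, dtype=float), right)


def evaluate_formula(formula: FeatureFormula, bindings: dict):
    """Evaluate element-wise over scalar or array bindings.

    Any non-finite intermediate (division by zero, negative sqrt, missing
    input) propagates to NaN in the result. Returns a float for all-scalar
    bindings, else an ndarray.
    """
    unbound = sorted(formula.variables - set(bindings))
    if unbound:
        raise ValueError(f"unbound variables in {formula.name!r}: {unbound}")
    result = np.asarray(_eval(formula.tree, bindings), dtype=float)
    result = np.where(np.isfinite(result), result, np.nan)
    if result.ndim == 0:
        return float(result)
    return result


# --- preset registry --------------------------------------------------------

_RGB_MS_PRESETS = {
    "BGI": "b/g",
    "BRI": "b/r",
    "CIVE": "r*0.441-g*0.811+b*0.385+18.78745",
    "EXG": "(g*2-r-b)/(r+g+b)",
    "EXR": "(r*1.4-g)/(r+g+b)",
    "EE": "EXG+EXR",
    "NDI": "(g-r)/(g+r)",
    "RGBI": "r/g",
    "RGBVI": "(g*g-b*r)/(g*g+b*r)",
    "VARI": "(g-r)/(g+r-b)",
}

_MS_ONLY_PRESETS = {
    "ARI": "(1/g)-(1/re)",
    "DVI": "nir-r",
    "GNDVI": "(nir-g)/(nir+g)",
    "MCARI1": "1.2*(2.5*(nir-r)-1.3*(nir-g))",
    # as printed in the source table: no ÷2 (see MSAVI_std variant)
    "MSAVI": "nir*2+1-sqrt((nir*2+1)^2-8*(nir-r))",
    "MSR": "(nir/r-1)/(nir/r+1)",
    "NDRE": "(nir-re)/(nir+re)",
    "NDVI": "(nir-r)/(nir+r)",
    "RDVI": "(nir-r)/sqrt(nir+r)",
    "OSAVI": "1.16*(nir-r)/(nir+r+0.16)",
    "RVI": "nir/r",
}

_VARIANTS = {
    "MSAVI_std": "(nir*2+1-sqrt((nir*2+1)^2-8*(nir-r)))/2",
}

_MS_ONLY_BANDS = {"re", "nir"}


class FormulaRegistry:
    """Preset index formulas keyed by name, gated by sensor class."""

    def __init__(self) -> None:
        self._entries: dict[str, FeatureFormula] = {}
        self._sensors: dict[str, frozenset] = {}
        for name, expr in _RGB_MS_PRESETS.items():
            self._add(name, expr, frozenset({"RGB", "MS"}))
        for name, expr in _MS_ONLY_PRESETS.items():
            self._add(name, expr, frozenset({"MS"}))
        self._variants: dict[str, FeatureFormula] = {
            name: parse_formula(name, expr) for name, expr in _VARIANTS.items()
        }

    def _add(self, name, expression, sensors) -> None:
        self._entries[name] = parse_formula(name, expression)
        self._sensors[name] = sensors

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def names(self, sensor: str | None = None) -> list[str]:
        if sensor is None:
            return list(self._entries)
        return [n for n, s in self._sensors.items() if sensor in s]

    def get(self, name: str, sensor: str) -> FeatureFormula:
        """Fetch a preset (or variant), enforcing the sensor gate."""
        formula = self._entries.get(name) or self._variants.get(name)
        if formula is None:
            raise KeyError(f"unknown preset index {name!r}")
        bands = self.band_variables(name)
        if sensor == "RGB" and bands & _MS_ONLY_BANDS:
            need = " and ".join(sorted(bands & _MS_ONLY_BANDS))
            raise ValueError(f"{name} requires {need} band(s); sensor is RGB")
        return formula

    def band_variables(self, name: str) -> set[str]:
        """Variables of a preset after inlining nested preset references."""
        return self.expand(name).variables - set()

    def expand(self, name: str) -> FeatureFormula:
        """Preset with references to other presets inlined (e.g. EE)."""
        formula = self._entries.get(name) or self._variants.get(name)
        if formula is None:
            raise KeyError(f"unknown preset index {name!r}")
        tree = self._expand_tree(formula.tree)
        expression = tree_to_expression(tree)
        variables: set[str] = set()
        _collect_variables(tree, variables)
        return FeatureFormula(name, expression, tree, frozenset(variables))

    def _expand_tree(self, tree):
        tag = tree[0]
        if tag == "var" and tree[1] in self._entries:
            return self._expand_tree(self._entries[tree[1]].tree)
        if tag == "neg":
            return ("neg", self._expand_tree(tree[1]))
        if tag == "call":
            return ("call", tree[1], self._expand_tree(tree[2]))
        if tag in ("add", "sub", "mul", "div", "pow"):
            return (tag, self._expand_tree(tree[1]), self._expand_tree(tree[2]))
        return tree


#: module-level registry instance preloaded with all presets
registry = FormulaRegistry()


def get_preset(name: str, sensor: str) -> FeatureFormula:
    """Shortcut for ``registry.get(name, sensor)``."""
    return registry.get(name, sensor)
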