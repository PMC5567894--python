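"""Mixed-model formula mini-language and design coding.

Grammar (a deliberately small subset of the Wilkinson/lme4 notation)::

    response ~ term1 + term2 + (expr1 + expr2 | group) + (1 | group2)

Fixed terms name design columns; the intercept is implicit (and "1" is
accepted inside random-effect groups).  Interactions (``:``/``*``), nesting
(``/``) and uncorrelated-slope syntax (``||``) are not part of the grammar:
random slopes are always modeled as correlated with their group intercept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelFormula", "CodedDesign", "parse_formula", "code_design"]

_NAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


@dataclass(frozen=True)
class ModelFormula:
    response: str
    fixed: tuple[str, ...]  # non-intercept fixed terms, in order
    random: tuple[tuple[tuple[str, ...], str], ...]  # ((exprs incl. "1"), group)

    def render(self) -> str:
        parts = list(self.fixed)
        for exprs, group in self.random:
            parts.append(f"({'+'.join(exprs)}|{group})")
        return f"{self.response}~{'+'.join(parts)}"


def _split_top_level(text: str, sep: str = "+") -> list[str]:
    """Split on sep outside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced parentheses")
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ValueError("unbalanced parentheses")
    parts.append("".join(cur))
    return [p.strip() for p in parts]


def parse_formula(text: str) -> ModelFormula:
    """Parse ``resp ~ a + b + (a|g) + (1|h)`` into a ModelFormula.

    Raises ValueError on unbalanced parentheses, unknown tokens, empty
    random-effect groups, or a fixed part with no non-intercept term.
    """
    if text.count("~") != 1:
        raise ValueError("formula must contain exactly one '~'")
    lhs, rhs = text.split("~")
    response = lhs.strip()
    if not _NAME.match(response):
        raise ValueError(f"invalid response name {response!r}")
    fixed: list[str] = []
    random: list[tuple[tuple[str, ...], str]] = []
    for part in _split_top_level(rhs):
        if not part:
            raise ValueError("empty term in formula")
        if part.startswith("("):
            if not part.endswith(")"):
                raise ValueError(f"malformed random term {part!r}")
            inner = part[1:-1]
            if inner.count("|") != 1:
                raise ValueError(f"random term must contain one '|': {part!r}")
            exprs_txt, group = (s.strip() for s in inner.split("|"))
            if not group or not _NAME.match(group):
                raise ValueError(f"invalid grouping factor in {part!r}")
            exprs = [e.strip() for e in exprs_txt.split("+")]
            if not exprs or any(not e for e in exprs):
                raise ValueError(f"empty random-effect expression in {part!r}")
            for e in exprs:
                if e != "1" and not _NAME.match(e):
                    raise ValueError(f"unknown token {e!r} in random term")
            # intercept always present and listed first
            ordered = ("1",) + tuple(e for e in exprs if e != "1")
            random.append((ordered, group))
        elif part == "1":
            continue  # intercept is implicit
        else:
            if not _NAME.match(part):
                raise ValueError(f"unknown token {part!r}")
            fixed.append(part)
    if not fixed:
        raise ValueError("at least one non-intercept fixed term is required")
    return ModelFormula(response, tuple(fixed), tuple(random))


@dataclass
class CodedDesign:
    """Numeric coding of the fixed part of a design table.

    ``matrix`` excludes the intercept (it is the X of the correlation step);
    model fitting prepends an intercept column itself.  Two-level factors
    are coded -0.5/+0.5 (-0.5 to the first level in sorted order); k>2-level
    factors expand to k-1 sum-to-zero contrast columns; numeric columns pass
    through unchanged.
    """

    matrix: np.ndarray  # trials x n_terms
    term_names: list[str]
    coding: dict[str, dict] = field(default_factory=dict)
    # source design column for each coded column (categoricals expand)
    source: list[str] = field(default_factory=list)


def _code_column(col: pd.Series, name: str) -> tuple[np.ndarray, list[str], dict | None]:
    if pd.api.types.is_numeric_dtype(col):
        vals = col.to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in continuous column {name!r}")
        if len(np.unique(vals)) < 2:
            raise ValueError(f"column {name!r} has a single unique value")
        return vals[:, None], [name], None
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"column {name!r} has a single unique level")
    vals = col.astype(str).to_numpy()
    if len(levels) == 2:
        mapping = {levels[0]: -0.5, levels[1]: 0.5}
        out = np.vectorize(mapping.get)(vals).astype(np.float64)
        return out[:, None], [name], {"levels": levels, "map": mapping}
    # sum-to-zero contrasts: column j is +1 for level j, -1 for the last level
    cols = []
    names = []
    for j, lev in enumerate(levels[:-1]):
        c = np.where(vals == lev, 1.0, np.where(vals == levels[-1], -1.0, 0.0))
        cols.append(c)
        names.append(f"{name}[{lev}]")
    return np.stack(cols, axis=1), names, {"levels": levels, "contrast": "sum"}


def code_design(formula: ModelFormula, design: pd.DataFrame) -> CodedDesign:
    """Build the numeric fixed-effects matrix for a design table."""
    mats, names, coding, source = [], [], {}, []
    for term in formula.fixed:
        if term not in design.columns:
            raise ValueError(f"formula term {term!r} not in design columns")
        m, ns, info = _code_column(design[term], term)
        mats.append(m)
        names.extend(ns)
        source.extend([term] * len(ns))
        if info is not None:
            coding[term] = info
    matrix = np.concatenate(mats, axis=1)
    return CodedDesign(matrix=matrix, term_names=names, coding=coding, source=source)
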