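"""Light-weight fixed-effect design matrix construction.

Supports the term language needed by the analysis models: numeric
covariates, categorical factors (treatment or sum-to-zero coding),
two-way interactions written ``a:b`` and squared terms written ``var^2``.
A :class:`DesignInfo` freezes the factor levels and coding so that the
same design can be rebuilt on new rows (used for slope contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignInfo", "build_design_info"]


def _is_categorical(s: pd.Series) -> bool:
    return (
        s.dtype == object
        or isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == bool
    )


@dataclass
class DesignInfo:
    """Frozen description of a fixed-effects design.

    Attributes
    ----------
    terms : list of str
        Model terms in order, not including the intercept.
    coding : str
        ``"treatment"`` (reference-level dummies) or ``"sum"``
        (sum-to-zero contrasts).
    ref_levels : dict
        Reference level per categorical variable.
    levels : dict
        Full, ordered level list per categorical variable (frozen from
        the data the design was built on).
    """

    terms: list[str]
    coding: str
    ref_levels: dict[str, str]
    levels: dict[str, list]
    column_names: list[str] = field(default_factory=list)
    term_columns: dict[str, list[int]] = field(default_factory=dict)

    def _part_columns(self, data: pd.DataFrame, part: str):
        """Columns and names contributed by one factor/covariate of a term."""
        if part in self.levels:  # categorical
            vals = data[part]
            ref = self.ref_levels[part]
            cols, names = [], []
            for lev in self.levels[part]:
                if lev == ref:
                    continue
                ind = (vals == lev).to_numpy(float)
                if self.coding == "sum":
                    ind = ind - (vals == ref).to_numpy(float)
                cols.append(ind)
                names.append(f"{part}[{lev}]")
            return cols, names
        if part.endswith("^2"):
            base = part[:-2]
            return [data[base].to_numpy(float) ** 2], [part]
        return [data[part].to_numpy(float)], [part]

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Build the design matrix (with leading intercept) for ``data``."""
        n = len(data)
        cols = [np.ones(n)]
        names = ["Intercept"]
        term_cols: dict[str, list[int]] = {"Intercept": [0]}
        for term in self.terms:
            parts = term.split(":")
            pc, pn = [np.ones(n)], [""]
            for part in parts:
                new_c, new_n = [], []
                part_c, part_n = self._part_columns(data, part)
                for c0, n0 in zip(pc, pn):
                    for c1, n1 in zip(part_c, part_n):
                        new_c.append(c0 * c1)
                        new_n.append(n1 if not n0 else f"{n0}:{n1}")
                pc, pn = new_c, new_n
            idx0 = len(cols)
            cols.extend(pc)
            names.extend(pn)
            term_cols[term] = list(range(idx0, len(cols)))
        self.column_names = names
        self.term_columns = term_cols
        return np.column_stack(cols)


def build_design_info(
    data: pd.DataFrame,
    terms: list[str],
    coding: str = "treatment",
    ref_levels: dict[str, str] | None = None,
) -> DesignInfo:
    """Infer factor levels from ``data`` and freeze a :class:`DesignInfo`.

    Interaction terms must name their main effects among ``terms``
    (checked), matching the marginality convention of the models.
    """
    if coding not in ("treatment", "sum"):
        raise ValueError(f"unknown coding {coding!r}")
    ref_levels = dict(ref_levels or {})
    levels: dict[str, list] = {}
    variables: set[str] = set()
    for term in terms:
        for part in term.split(":"):
            variables.add(part)
    for term in terms:
        parts = term.split(":")
        if len(parts) > 1:
            for part in parts:
                if part not in terms:
                    raise ValueError(
                        f"interaction {term!r} requires main effect {part!r}"
                    )
    for var in sorted(variables):
        base = var[:-2] if var.endswith("^2") else var
        if base not in data.columns:
            raise KeyError(f"variable {base!r} not in data")
        if not var.endswith("^2") and _is_categorical(data[var]):
            lev = sorted(pd.unique(data[var].dropna()))
            levels[var] = lev
            ref_levels.setdefault(var, lev[0])
    return DesignInfo(
        terms=list(terms), coding=coding, ref_levels=ref_levels, levels=levels
    )
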