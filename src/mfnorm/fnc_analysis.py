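"""Functional network connectivity (FNC) and group comparison.

FNC summarizes, per subject, the pairwise Pearson correlation between
component timecourses.  Group differences (e.g. healthy controls vs
patients) are tested per component pair with a two-sample t-test on
Fisher-z-transformed correlations and corrected over the pair family with
Benjamini–Hochberg FDR (default q = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network_eval import fdr_threshold

__all__ = ["FncMatrix", "compute_fnc", "group_compare"]


@dataclass
class FncMatrix:
    """Symmetric component-by-component correlation matrix for one subject."""

    values: np.ndarray
    component_names: list[str]
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        c = len(self.component_names)
        if self.values.shape != (c, c):
            raise ValueError("values shape does not match component count")

    def pair(self, a: str, b: str) -> float:
        i = self.component_names.index(a)
        j = self.component_names.index(b)
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        i, j = np.triu_indices(len(self.component_names), k=1)
        return self.values[i, j]


def compute_fnc(
    timecourses: np.ndarray,
    component_names: list[str] | None = None,
    subject_id: str | None = None,
    group: str | None = None,
) -> FncMatrix:
    """Pairwise Pearson correlations of a (components x T) matrix.

    Constant rows yield NaN in all their pairs (their correlation is
    undefined); the diagonal is 1 for non-constant components.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2:
        raise ValueError("timecourses must be a 2-D (components x T) matrix")
    c, t = tc.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    names = component_names or [f"comp_{i}" for i in range(c)]
    sd = tc.std(axis=1)
    constant = sd == 0
    vals = np.full((c, c), np.nan)
    ok = ~constant
    if ok.sum() >= 1:
        sub = np.corrcoef(tc[ok]) if ok.sum() > 1 else np.ones((1, 1))
        vals[np.ix_(ok, ok)] = sub
    return FncMatrix(vals, list(names), subject_id=subject_id, group=group)


def group_compare(
    group_a: list[FncMatrix],
    group_b: list[FncMatrix],
    q: float = 0.05,
    fisher_z: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per component pair with BH-FDR over the family.

    Returns a DataFrame with one row per unique pair: t (a minus b), raw p,
    and the FDR rejection flag at level q.  Correlations are Fisher-z
    transformed before testing by default.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    names = group_a[0].component_names
    for m in group_a + group_b:
        if m.component_names != names:
            raise ValueError("component sets differ between subjects")
    i_idx, j_idx = np.triu_indices(len(names), k=1)

    def stack(group: list[FncMatrix]) -> np.ndarray:
        vals = np.stack([m.values[i_idx, j_idx] for m in group])
        if fisher_z:
            vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
        return vals

    a = stack(group_a)
    b = stack(group_b)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    reject, _ = fdr_threshold(p, q)
    return pd.DataFrame(
        {
            "component_a": [names[i] for i in i_idx],
            "component_b": [names[j] for j in j_idx],
            "t": t,
            "p": p,
            "reject": reject,
        }
    )
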