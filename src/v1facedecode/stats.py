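"""Univariate inference: repeated-measures ANOVA and Holm-Bonferroni.

``rm_anova`` is the within-subject factorial decomposition in which each
effect is tested against its own effect-by-subject interaction,
``F = MS_effect / MS_(effect x subject)`` with numerator dof the product of
(levels - 1) and denominator dof ``numerator x (n_subjects - 1)`` — for nine
subjects and two-level factors this gives the F(1, 8) layout.  All factors
used here have at most three levels; sphericity corrections are omitted
because two-level factors satisfy sphericity trivially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = ["AnovaResult", "rm_anova", "holm_bonferroni"]


@dataclass
class AnovaResult:
    """Per-effect F, dof pair and p, with a flag for degenerate (zero
    error-variance) effects reported as F = 0."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        hit = self.table.loc[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect named {name!r}")
        return hit.iloc[0]


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factors: list[str] | None = None,
) -> AnovaResult:
    """Fully within-subject repeated-measures ANOVA (up to three factors).

    ``data`` is long-format with one row per subject x factor-level cell; the
    design must be balanced and complete (exactly one observation per cell).
    """
    if factors is None or not factors:
        raise ValueError("at least one within-subject factor is required")
    n_subjects = data[subject].nunique()
    if n_subjects < 2:
        raise ValueError("at least two subjects are required")
    counts = data.groupby([subject] + list(factors), observed=True)[dv].count()
    expected_cells = n_subjects * int(np.prod([data[f].nunique() for f in factors]))
    if len(counts) != expected_cells or (counts != 1).any():
        raise ValueError("unbalanced design: need exactly one observation per subject x cell")
    fit = AnovaRM(data, depvar=dv, subject=subject, within=list(factors)).fit()
    tab = fit.anova_table
    rows = []
    for effect, row in tab.iterrows():
        F = row["F Value"]
        # zero error variance yields non-finite (or numerically negative) F
        degenerate = (not np.isfinite(F)) or F < 0
        rows.append(
            {
                "effect": effect,
                "F": 0.0 if degenerate else float(F),
                "df1": int(row["Num DF"]),
                "df2": int(row["Den DF"]),
                "p": 1.0 if degenerate else float(row["Pr > F"]),
                "degenerate": degenerate,
            }
        )
    return AnovaResult(table=pd.DataFrame(rows))


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down family-wise error control.

    Sort p ascending and reject while ``p(i) <= alpha / (m - i + 1)``,
    stopping at the first failure.  Returns a boolean rejection mask in the
    original order (empty input gives an empty mask).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject
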