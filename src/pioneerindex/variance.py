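"""Variance partitioning of dox50 by accessibility and chromatin marks.

How much of the site-to-site spread in binding affinity does chromatin
state explain?  An ordinary-least-squares model of dox50 on categorical
factors (``dox50 ~ C(accessibility)``, optionally extended with one
chromatin mark and its interaction) is decomposed by sequential (Type I)
sums of squares; each term's share of the total sum of squares is its
variance fraction (for a single two-level factor this is the classical
eta-squared).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "anova_variance_fractions",
    "accessibility_variance_report",
]


def _check_design(df: pd.DataFrame, factors: Sequence[str]) -> None:
    if not np.isfinite(df["response"]).all():
        raise ValueError("non-finite response values")
    for f in factors:
        if df[f].isna().any():
            raise ValueError(f"factor {f!r} has missing values")
        levels = df[f].astype(str).value_counts()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has a single level")
        if (levels < 2).any():
            raise ValueError(f"factor {f!r} has a level with < 2 rows")


def anova_variance_fractions(
    rows: pd.DataFrame,
    factors: Sequence[str],
    interaction: bool = False,
    log_response: bool = False,
) -> dict[str, float]:
    """Per-term variance fractions from a sequential (Type I) ANOVA.

    Parameters
    ----------
    rows
        DataFrame with a ``response`` column (dox50) plus one column per
        factor (categorical).
    factors
        Factor names, entered into the model in this order — with
        sequential sums of squares the order matters for non-orthogonal
        designs.
    interaction
        Add the all-way interaction of ``factors`` as a final term.
    log_response
        Model log(dox50) instead of the raw scale (dox50 is a positive
        scale parameter; the default keeps the raw scale).

    Returns
    -------
    dict mapping each term (and ``"residual"``) to SS_term / SS_total.
    Fractions lie in [0, 1] and sum to 1.
    """
    df = rows.copy()
    _check_design(df, factors)
    if log_response:
        df["response"] = np.log(df["response"])
    terms = [f"C({f})" for f in factors]
    if interaction:
        terms.append(":".join(f"C({f})" for f in factors))
    formula = "response ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    table = sm.stats.anova_lm(model, typ=1)
    ss_total = float(table["sum_sq"].sum())
    fractions = {
        term: float(ss) / ss_total
        for term, ss in table["sum_sq"].items()
        if term != "Residual"
    }
    fractions["residual"] = float(table.loc["Residual", "sum_sq"]) / ss_total
    return fractions


def accessibility_variance_report(
    dox50s: Mapping[str, float],
    accessibility: Mapping[str, str],
    mark_flags: pd.DataFrame | None = None,
    log_response: bool = False,
) -> pd.DataFrame:
    """Variance fractions for the accessibility model and its mark extensions.

    Fits ``dox50 ~ C(accessibility)`` first, then — for each mark column in
    ``mark_flags`` — the extended model with the mark and the
    accessibility x mark interaction (terms entered in that order,
    sequential SS).  Sites lacking a dox50 or a label are dropped.

    Returns a tidy frame: model, term, fraction.
    """
    base = pd.DataFrame(
        {
            "site_id": list(dox50s),
            "response": [dox50s[s] for s in dox50s],
            "accessibility": [accessibility.get(s) for s in dox50s],
        }
    ).dropna(subset=["response", "accessibility"])
    base = base.set_index("site_id")
    out = []
    fr = anova_variance_fractions(base, ["accessibility"], log_response=log_response)
    out += [
        {"model": "accessibility", "term": t, "fraction": v} for t, v in fr.items()
    ]
    if mark_flags is not None:
        for mark in mark_flags.columns:
            if mark_flags[mark].dtype == object:
                continue
            df = base.join(mark_flags[mark].astype(bool), how="inner")
            try:
                fr = anova_variance_fractions(
                    df, ["accessibility", mark], interaction=True,
                    log_response=log_response,
                )
            except ValueError:
                # e.g. a mark absent from one accessibility class entirely
                continue
            out += [
                {"model": f"accessibility+{mark}", "term": t, "fraction": v}
                for t, v in fr.items()
            ]
    return pd.DataFrame(out)
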