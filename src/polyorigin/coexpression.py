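"""Gene-expression vs. metabolite correlation screening.

Matches expression samples (genes x samples, FPKM) to a metabolite
concentration profile over shared (tissue, condition) labels, averages
replicate measurements per label, computes a Pearson r per gene (optionally
on log10(x+1)-transformed expression) and ranks candidates above a
correlation threshold.  No multiple-testing correction is applied: the
screen selects by correlation magnitude, as the underlying field practice
does; sample counts are carried in the report for downstream use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["match_samples", "correlate", "screen", "ScreenResult"]


def match_samples(
    expression: pd.DataFrame, metabolite: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Align expression columns and metabolite entries on shared labels.

    Replicate measurements (duplicate sample labels) are averaged per label
    before pairing.  Requires at least 3 common labels.
    """
    expr = expression.T.groupby(level=0).mean().T if expression.columns.has_duplicates else expression
    metab = metabolite.groupby(level=0).mean() if metabolite.index.has_duplicates else metabolite
    common = [c for c in expr.columns if c in set(metab.index)]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 common sample labels, found {len(common)}"
        )
    return expr[common], metab.loc[common]


def correlate(
    expression: pd.DataFrame,
    metabolite: pd.Series,
    transform: str = "none",
) -> pd.DataFrame:
    """Pearson r of every gene's expression against the metabolite profile.

    Parameters
    ----------
    transform
        "none" or "log10"; log10 applies ``log10(x + 1)`` to expression
        values before correlating (concentrations are left untouched).

    Returns
    -------
    DataFrame indexed by gene id with columns ``r``, ``n`` and
    ``transform``.  Genes with zero expression variance have undefined r
    and are excluded with a warning.
    """
    expr, metab = match_samples(expression, metabolite)
    if transform == "log10":
        x = np.log10(expr.to_numpy(dtype=float) + 1.0)
    elif transform == "none":
        x = expr.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    y = metab.to_numpy(dtype=float)
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    if sy == 0:
        raise ValueError("metabolite profile is constant; r undefined for all genes")
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant-expression gene(s) with undefined r"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    hits = pd.DataFrame(
        {"r": r, "n": n, "transform": transform}, index=expr.index
    )
    return hits.loc[~constant]


@dataclass
class ScreenResult:
    candidates: pd.DataFrame  # genes with r >= r_min, sorted descending
    r_min: float
    n_samples: int
    transform: str

    def gene_ids(self) -> list[str]:
        return list(self.candidates.index)


def screen(hits: pd.DataFrame, r_min: float = 0.9) -> ScreenResult:
    """Rank genes with r >= r_min, descending (ties break by gene id)."""
    passed = hits[hits["r"] >= r_min]
    # stable sort: descending r, ties broken by gene id
    ordered = passed.sort_index().sort_values(by="r", ascending=False, kind="mergesort")
    n = int(hits["n"].iloc[0]) if len(hits) else 0
    transform = str(hits["transform"].iloc[0]) if len(hits) else "none"
    return ScreenResult(ordered, r_min, n, transform)
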