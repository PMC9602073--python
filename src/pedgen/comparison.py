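"""Pairwise Pearson correlations among inbreeding estimators with
significance stars."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAR_CUTOFFS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    if np.isnan(p):
        return "NA"
    for cutoff, mark in STAR_CUTOFFS:
        if p < cutoff:
            return mark
    return "ns"


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int

    def table(self) -> pd.DataFrame:
        """r above the diagonal, significance stars below."""
        cols = self.r.columns
        out = pd.DataFrame("", index=cols, columns=cols)
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                if i < j:
                    out.loc[a, b] = f"{self.r.loc[a, b]:.2f}"
                elif i > j:
                    out.loc[a, b] = self.stars.loc[a, b]
        return out


def correlation_matrix(m: pd.DataFrame) -> CorrelationResult:
    """Pearson r with two-sided p-values among estimator columns.

    Rows with any missing value are dropped (listwise deletion); p-values
    come from the t transform t = r·sqrt((n-2)/(1-r²)) on n-2 degrees of
    freedom.  Zero-variance columns yield NaN correlations with a warning.
    """
    data = m.dropna(axis=0)
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 complete rows, got {n}")
    cols = list(data.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            x = data.iloc[:, i].to_numpy(dtype=float)
            y = data.iloc[:, j].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                if i <= j:
                    warnings.warn(
                        f"zero-variance column in pair ({cols[i]}, {cols[j]}); r undefined"
                    )
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = rij
            if abs(rij) >= 1.0:
                p[i, j] = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij * rij))
                p[i, j] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pdf.map(stars_for_p)
    return CorrelationResult(r=rdf, p=pdf, stars=sdf, n=n)


def estimator_matrix(
    fped: pd.Series | None,
    fgrm: pd.Series | None,
    froh: pd.Series | None,
    froh_by_min_length: pd.DataFrame | None,
) -> pd.DataFrame:
    """Assemble the animal x estimator table (index = animal id)."""
    parts = {}
    if fped is not None:
        parts["FPED"] = fped
    if fgrm is not None:
        parts["FGRM"] = fgrm
    if froh is not None:
        parts["FROH"] = froh
    df = pd.DataFrame(parts)
    if froh_by_min_length is not None:
        renames = {
            c: "FROH>" + c.replace("froh_ge_", "").replace("mb", " Mb")
            for c in froh_by_min_length.columns
        }
        df = df.join(froh_by_min_length.rename(columns=renames), how="outer")
    return df
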