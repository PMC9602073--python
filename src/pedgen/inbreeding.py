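"""Pedigree inbreeding, average relatedness, individual rates of inbreeding
and realized effective population size.

The workhorse is the Meuwissen & Luo ancestor-tracing algorithm, which
computes per-animal inbreeding coefficients in linear memory via the
L/D (Cholesky) decomposition of the numerator relationship matrix A.
A dense tabular-method construction of A is kept as an independent oracle
for testing and for small pedigrees.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

#: floating-point guard used when counting "inbred" animals (F > 0)
INBRED_EPS = 1e-12


@dataclass
class PedigreeInbreedingResult:
    """Per-animal F / AR / ΔF plus population summaries."""

    ids: list[str]
    f: np.ndarray
    ar: np.ndarray
    delta_f: np.ndarray  # nan where undefined (EqG <= 1)
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "f": self.f, "ar": self.ar, "delta_f": self.delta_f}
        )


def _mendelian_variance(f: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variances d_i given parental F.

    d_i = 0.5 - 0.25(F_s + F_d); a missing parent contributes F = -1
    (equivalently d gains 0.25), so founders get d = 1.
    """
    fs = np.where(sire != UNKNOWN, f[sire], -1.0)
    fd = np.where(dam != UNKNOWN, f[dam], -1.0)
    return 0.5 - 0.25 * (fs + fd)


def inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (diag(A) - 1).

    Processes animals in topological order; for each animal with both
    parents known, traces its ancestors accumulating the squared L
    coefficients weighted by the ancestors' Mendelian sampling variances.
    Memory is linear in pedigree size; A is never materialized.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    d = np.empty(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        d[i] = 0.5 - 0.25 * ((f[s] if s != UNKNOWN else -1.0) + (f[dm] if dm != UNKNOWN else -1.0))
        if s == UNKNOWN or dm == UNKNOWN:
            continue
        # trace ancestors of i, highest index first (heap of negated indices)
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = coeff.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p == UNKNOWN:
                    continue
                if p in coeff:
                    coeff[p] += 0.5 * lj
                else:
                    coeff[p] = 0.5 * lj
                    heapq.heappush(heap, -p)
        f[i] = aii - 1.0
    return f


def relationship_matrix_oracle(ped: Pedigree, cap: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    a_ii = 1 + 0.5*a_{sire,dam}; a_ij = 0.5*(a_{j,sire(i)} + a_{j,dam(i)})
    for j preceding i. Intended as a test oracle and for small pedigrees.
    """
    n = ped.n
    if n > cap:
        raise ValueError(
            f"pedigree size {n} exceeds oracle cap {cap}; "
            "use inbreeding_meuwissen_luo / average_relatedness instead"
        )
    sire, dam = ped.sire, ped.dam
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            a[i, :i] = 0.5 * (a[s, :i] + a[d, :i])
            a[i, i] = 1.0 + 0.5 * a[s, d]
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            a[i, :i] = 0.5 * a[p, :i]
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0
        a[:i, i] = a[i, :i]
    return a


def average_relatedness(ped: Pedigree, f: np.ndarray | None = None) -> np.ndarray:
    """Per-animal average relatedness AR_i = (Σ_j a_ij) / (2n).

    AR_i is the probability that an allele drawn at random from the whole
    pedigree traces to animal i.  Row sums of A are obtained without a dense
    matrix through A = T D T': back-propagate T'1 through offspring, scale
    by D, and push forward through parents.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    if f is None:
        f = inbreeding_meuwissen_luo(ped)
    d = _mendelian_variance(f, sire, dam)
    # u = T'1: total expected flow of each animal's genes into the pedigree
    u = np.ones(n)
    for i in range(n - 1, -1, -1):
        if sire[i] != UNKNOWN:
            u[sire[i]] += 0.5 * u[i]
        if dam[i] != UNKNOWN:
            u[dam[i]] += 0.5 * u[i]
    v = d * u
    rowsum = np.empty(n)
    for i in range(n):
        acc = v[i]
        if sire[i] != UNKNOWN:
            acc += 0.5 * rowsum[sire[i]]
        if dam[i] != UNKNOWN:
            acc += 0.5 * rowsum[dam[i]]
        rowsum[i] = acc
    return rowsum / (2.0 * n)


def individual_delta_f(
    f: np.ndarray, eqg: np.ndarray, include_all: bool = False
) -> tuple[np.ndarray, float, float | None, int]:
    """Individual rates of inbreeding and realized effective population size.

    ΔF_i = 1 - (1 - F_i)^(1/(EqG_i - 1)), defined only for EqG_i > 1;
    Ne = 1/(2·mean ΔF).

    Parameters
    ----------
    include_all : bool
        If True, animals with EqG <= 1 enter the mean with ΔF = 0 instead of
        being excluded.

    Returns
    -------
    delta_f : ndarray  (nan where undefined)
    mean_delta_f : float
    ne : float or None  (None when the mean is not positive or no animal qualifies)
    n_excluded : int
    """
    f = np.asarray(f, dtype=float)
    eqg = np.asarray(eqg, dtype=float)
    delta = np.full(f.shape, np.nan)
    ok = eqg > 1.0
    delta[ok] = 1.0 - np.power(1.0 - f[ok], 1.0 / (eqg[ok] - 1.0))
    n_excluded = int((~ok).sum())
    if include_all:
        vals = np.where(ok, delta, 0.0)
    else:
        vals = delta[ok]
    if vals.size == 0:
        return delta, float("nan"), None, n_excluded
    mean = float(np.mean(vals))
    ne = 1.0 / (2.0 * mean) if mean > 0 else None
    return delta, mean, ne, n_excluded


def analyze_pedigree_inbreeding(
    ped: Pedigree, eqg: np.ndarray, include_all_in_delta_f: bool = False
) -> PedigreeInbreedingResult:
    """Full per-animal + summary inbreeding analysis of one pedigree."""
    f = inbreeding_meuwissen_luo(ped)
    ar = average_relatedness(ped, f)
    delta, mean_delta, ne, n_excl = individual_delta_f(f, eqg, include_all_in_delta_f)
    inbred = f > INBRED_EPS
    summary = {
        "n": ped.n,
        "mean_f": float(np.mean(f)),
        "pct_inbred": float(100.0 * np.mean(inbred)),
        "mean_f_inbred": float(np.mean(f[inbred])) if inbred.any() else 0.0,
        "mean_ar": float(np.mean(ar)),
        "mean_delta_f": mean_delta,
        "ne": ne,
        "n_excluded_delta_f": n_excl,
    }
    return PedigreeInbreedingResult(ids=list(ped.ids), f=f, ar=ar, delta_f=delta, summary=summary)


def mean_f_from_inbred(mean_f_inbred: float, fraction_inbred: float) -> float:
    """Population mean F reconstructed from the inbred-animal mean and the
    inbred fraction: mean F = mean(F | inbred) × P(inbred)."""
    return mean_f_inbred * fraction_inbred
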