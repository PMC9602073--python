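"""Pedigree depth metrics and generation intervals.

Equivalent complete generations, maximum/complete generations traced, the
per-depth pedigree completeness index, and generation intervals along the
four parent-offspring selection paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

#: selection paths: (parent role, offspring role)
PATHS = ("SS", "SD", "DS", "DD")

_PATH_LABELS = {
    "SS": "Sire-Sire",
    "SD": "Sire-Dam",
    "DS": "Dam-Sire",
    "DD": "Dam-Dam",
}


def equivalent_generations(ped: Pedigree) -> np.ndarray:
    """EqG_i = Σ over known ancestors of (1/2)^n, n = path length.

    Computed by the forward recursion
    EqG_i = Σ_{p in known parents} 0.5·(1 + EqG_p); founders get 0.
    A fully known g-generation pedigree gives exactly g.
    """
    n = ped.n
    eqg = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                acc += 0.5 * (1.0 + eqg[p])
        eqg[i] = acc
    return eqg


def generations_traced(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """(maxg, comg): longest ancestor path, and deepest fully-known generation.

    comg_i is the largest g such that all 2^g ancestors at depth g are known:
    comg_i = 1 + min(comg_sire, comg_dam) when both parents are known, else 0.
    """
    n = ped.n
    maxg = np.zeros(n, dtype=np.int64)
    comg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        m = 0
        if s != UNKNOWN:
            m = max(m, 1 + maxg[s])
        if d != UNKNOWN:
            m = max(m, 1 + maxg[d])
        maxg[i] = m
        comg[i] = 1 + min(comg[s], comg[d]) if (s != UNKNOWN and d != UNKNOWN) else 0
    return maxg, comg


def _known_ancestor_counts(ped: Pedigree, depth: int) -> np.ndarray:
    """k[i, g] = number of known ancestors of animal i at generation g
    (g = 0 counts the animal itself; maximum 2^g)."""
    n = ped.n
    k = np.zeros((n, depth + 1), dtype=float)
    k[:, 0] = 1.0
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                k[i, 1:] += k[p, :-1]
    return k


def completeness_index(ped: Pedigree, depth: int) -> np.ndarray:
    """Pedigree completeness index PCI(d) for d = 1..depth, per animal.

    For each parental line the completeness to depth d is the mean over
    generations 1..d of (known ancestors at that generation) / 2^(g-1),
    where generation 1 is the parent itself.  The two line values are
    combined by their harmonic mean, which is 0 whenever either parent is
    unknown.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = ped.n
    k = _known_ancestor_counts(ped, depth - 1)
    denom = 2.0 ** np.arange(depth)  # 2^(g-1) for g = 1..depth
    pci = np.zeros((n, depth))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        cs = np.cumsum(k[s, :depth] / denom) / np.arange(1, depth + 1) if s != UNKNOWN else np.zeros(depth)
        cd = np.cumsum(k[d, :depth] / denom) / np.arange(1, depth + 1) if d != UNKNOWN else np.zeros(depth)
        tot = cs + cd
        nz = tot > 0
        pci[i, nz] = 2.0 * cs[nz] * cd[nz] / tot[nz]
    return pci


@dataclass
class PathStats:
    """Count, mean and standard error of one selection path's intervals."""

    n: int
    mean: float
    se: float


@dataclass
class GenerationIntervalSummary:
    """Per-path generation intervals plus overall means.

    ``overall_weighted`` is the count-weighted mean across paths (the
    convention behind a combined "Total" row); ``overall_unweighted`` is the
    simple mean of the four path means.
    """

    paths: dict[str, PathStats]
    n_skipped_missing_year: int = 0

    @property
    def total_n(self) -> int:
        return sum(p.n for p in self.paths.values())

    def overall_weighted(self) -> float:
        num = sum(p.n * p.mean for p in self.paths.values() if p.n > 0)
        den = sum(p.n for p in self.paths.values())
        if den == 0:
            return float("nan")
        return num / den

    def overall_unweighted(self) -> float:
        means = [p.mean for p in self.paths.values() if p.n > 0]
        if not means:
            return float("nan")
        return float(np.mean(means))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "path": _PATH_LABELS[p],
                "n": st.n,
                "mean": st.mean,
                "se": st.se,
            }
            for p, st in self.paths.items()
        ]
        rows.append(
            {
                "path": "Total",
                "n": self.total_n,
                "mean": self.overall_weighted(),
                "se": float("nan"),
            }
        )
        return pd.DataFrame(rows)


def generation_intervals(ped: Pedigree) -> GenerationIntervalSummary:
    """Generation intervals along the four selection paths.

    A (parent, offspring) pair is counted only when the offspring itself has
    recorded progeny ("kept for reproduction").  The offspring's role (sire
    vs dam side) is determined by how it appears as a parent; the interval
    is offspring birth year minus parent birth year.  Pairs with a missing
    birth year on either side are skipped and counted.
    """
    n = ped.n
    appears_as_sire = np.zeros(n, dtype=bool)
    appears_as_dam = np.zeros(n, dtype=bool)
    for i in range(n):
        if ped.sire[i] != UNKNOWN:
            appears_as_sire[ped.sire[i]] = True
        if ped.dam[i] != UNKNOWN:
            appears_as_dam[ped.dam[i]] = True
    intervals: dict[str, list[float]] = {p: [] for p in PATHS}
    skipped = 0
    for i in range(n):
        offspring_roles = []
        if appears_as_sire[i]:
            offspring_roles.append("S")
        if appears_as_dam[i]:
            offspring_roles.append("D")
        if not offspring_roles:
            continue  # no progeny: not on any path
        for parent, role in ((ped.sire[i], "S"), (ped.dam[i], "D")):
            if parent == UNKNOWN:
                continue
            yo, yp = ped.birth_year[i], ped.birth_year[parent]
            for orole in offspring_roles:
                if np.isnan(yo) or np.isnan(yp):
                    skipped += 1
                    continue
                intervals[role + orole].append(yo - yp)
    paths = {}
    for p in PATHS:
        vals = np.asarray(intervals[p], dtype=float)
        if vals.size == 0:
            paths[p] = PathStats(n=0, mean=float("nan"), se=float("nan"))
        else:
            se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
            paths[p] = PathStats(n=int(vals.size), mean=float(vals.mean()), se=se)
    return GenerationIntervalSummary(paths=paths, n_skipped_missing_year=skipped)


def depth_metrics_frame(ped: Pedigree, pci_depth: int = 5) -> pd.DataFrame:
    """Per-animal table of EqG, MaxG, ComG and PCI(1..pci_depth)."""
    eqg = equivalent_generations(ped)
    maxg, comg = generations_traced(ped)
    pci = completeness_index(ped, pci_depth)
    df = pd.DataFrame({"id": ped.ids, "eqg": eqg, "maxg": maxg, "comg": comg})
    for d in range(pci_depth):
        df[f"pci_{d + 1}"] = pci[:, d]
    return df
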