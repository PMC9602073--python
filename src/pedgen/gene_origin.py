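"""Probability of gene origin: founder contributions, effective number of
founders, greedy marginal ancestor contributions and effective number of
ancestors.

Founders are animals with both parents unknown.  A non-founder with one
unknown parent contributes a phantom founder for that side, so expected
founder contributions always sum to one over a reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, ReferencePopulation

#: residual tolerance at which ancestor extraction stops
RESIDUAL_TOL = 1e-10


@dataclass
class GeneOriginResult:
    """Founder and marginal ancestor contributions for a reference population.

    ``q`` maps founder id (or phantom key ``"<id>#sire"`` / ``"<id>#dam"``)
    to its expected proportional contribution; ``p`` is the ordered list of
    (ancestor id, marginal contribution) in selection order.
    """

    q: dict[str, float]
    p: list[tuple[str, float]]
    fe: float
    fa: float
    n_half: int | None
    ties: list[str] = field(default_factory=list)

    @property
    def fa_fe_ratio(self) -> float:
        return fa_fe_ratio(self.fa, self.fe)

    def ancestor_frame(self) -> pd.DataFrame:
        cum = np.cumsum([v for _, v in self.p])
        return pd.DataFrame(
            {
                "id": [a for a, _ in self.p],
                "marginal_contribution": [v for _, v in self.p],
                "cumulative": cum,
            }
        )


def fa_fe_ratio(fa: float, fe: float) -> float:
    """Ratio of effective ancestors to effective founders (< 1 under bottlenecks)."""
    return fa / fe


def effective_number(contributions) -> float:
    """1 / Σ c_i² — effective number of equal contributors."""
    c = np.asarray(list(contributions), dtype=float)
    return float(1.0 / np.sum(c * c))


def _ref_weights(ped: Pedigree, ref: ReferencePopulation) -> np.ndarray:
    if not ref.ids:
        raise ValueError("reference population is empty")
    w = np.zeros(ped.n)
    for a in ref.ids:
        w[ped.index_of(a)] += 1.0 / len(ref.ids)
    return w


def _backpropagate(
    ped: Pedigree, w0: np.ndarray, blocked: np.ndarray | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """Flow of expected reference-genome fractions up the pedigree.

    Returns per-animal arriving flow and the fractions absorbed by phantom
    founders (unknown parent slots of non-founders).  Flow is not propagated
    above animals flagged in ``blocked`` (nor above founders).
    """
    n = ped.n
    flow = w0.astype(float).copy()
    phantom: dict[str, float] = {}
    founder = ped.is_founder
    for i in range(n - 1, -1, -1):
        if flow[i] == 0.0 or founder[i] or (blocked is not None and blocked[i]):
            continue
        half = 0.5 * flow[i]
        for p, side in ((ped.sire[i], "sire"), (ped.dam[i], "dam")):
            if p != UNKNOWN:
                flow[p] += half
            else:
                key = f"{ped.ids[i]}#{side}"
                phantom[key] = phantom.get(key, 0.0) + half
    return flow, phantom


def founder_contributions(
    ped: Pedigree, ref: ReferencePopulation
) -> tuple[dict[str, float], float]:
    """Expected founder contributions q and the effective number of founders.

    q_f is the expected fraction of a reference animal's genome originating
    from founder f, averaged over the reference population; Fe = 1/Σq².
    """
    w0 = _ref_weights(ped, ref)
    flow, phantom = _backpropagate(ped, w0)
    q: dict[str, float] = {}
    for i in np.flatnonzero(ped.is_founder):
        if flow[i] > 0:
            q[ped.ids[i]] = float(flow[i])
    q.update(phantom)
    total = sum(q.values())
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"founder contributions sum to {total}, expected 1")
    return q, effective_number(q.values())


def _explained_fraction(ped: Pedigree, selected: np.ndarray) -> np.ndarray:
    """g[i] = expected fraction of animal i's genome tracing through a
    selected ancestor (upward paths stop at the first selected animal)."""
    n = ped.n
    g = np.zeros(n)
    for i in range(n):
        if selected[i]:
            g[i] = 1.0
            continue
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                g[i] += 0.5 * g[p]
    return g


def boichard_marginal_contributions(
    ped: Pedigree,
    ref: ReferencePopulation,
    max_ancestors: int | None = None,
    tol: float = RESIDUAL_TOL,
) -> GeneOriginResult:
    """Greedy extraction of the major ancestors of a reference population.

    Each round computes every candidate's expected contribution to the
    reference genes not yet explained by previously selected ancestors
    (selected ancestors' parent links are severed, and a candidate's own
    genome fraction already explained is discounted), then selects the
    maximum.  Fa = 1/Σp² over the extracted marginal contributions; n_half
    is the number of ancestors needed to explain half the gene pool.
    """
    n = ped.n
    w0 = _ref_weights(ped, ref)
    q, fe = founder_contributions(ped, ref)
    if max_ancestors is None:
        max_ancestors = n
    # candidates: strict ancestors of the reference, plus reference animals
    # that are themselves gene origins (founders, or holders of an unknown
    # parent slot whose genes no true ancestor can explain)
    candidate = np.zeros(n, dtype=bool)
    has_unknown = (ped.sire == UNKNOWN) | (ped.dam == UNKNOWN)
    for a in ref.ids:
        i = ped.index_of(a)
        if has_unknown[i]:
            candidate[i] = True
        stack = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        while stack:
            j = stack.pop()
            if candidate[j]:
                continue
            candidate[j] = True
            stack.extend(p for p in (ped.sire[j], ped.dam[j]) if p != UNKNOWN)
    selected = np.zeros(n, dtype=bool)
    p_list: list[tuple[str, float]] = []
    ties: list[str] = []
    residual = 1.0
    while len(p_list) < max_ancestors and residual > tol:
        flow, _ = _backpropagate(ped, w0, blocked=selected)
        g = _explained_fraction(ped, selected)
        marginal = flow * (1.0 - g)
        marginal[selected | ~candidate] = -np.inf
        best = int(np.argmax(marginal))  # argmax takes the smallest index on ties
        best_val = float(marginal[best])
        if best_val <= tol:
            break
        if np.sum(np.isclose(marginal, best_val, rtol=0, atol=1e-12)) > 1:
            ties.append(ped.ids[best])
        selected[best] = True
        p_list.append((ped.ids[best], best_val))
        residual -= best_val
    fa = effective_number(v for _, v in p_list)
    cum = np.cumsum([v for _, v in p_list])
    half = np.flatnonzero(cum >= 0.5 - 1e-12)
    n_half = int(half[0]) + 1 if half.size else None
    return GeneOriginResult(q=q, p=p_list, fe=fe, fa=fa, n_half=n_half, ties=ties)
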