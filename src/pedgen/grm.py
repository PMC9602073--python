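"""Genomic relationship matrix (Yang et al. estimator) and FGRM.

FGRM is the GRM diagonal minus one.  With sample allele frequencies the
estimator is frequency-sensitive: FGRM is bounded below by -1 but unbounded
above, and its population mean can be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypePanel


@dataclass
class GenomicRelationshipResult:
    ids: list[str]
    g: np.ndarray          # animal x animal
    fgrm: np.ndarray       # diag(G) - 1
    freqs: np.ndarray      # per-SNP A1 frequency used (nan for monomorphic/all-missing)
    n_snps_used: int

    def fgrm_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "fgrm": self.fgrm})


def build_grm_yang(
    panel: GenotypePanel, freqs: np.ndarray | None = None
) -> GenomicRelationshipResult:
    """GRM with SNP-specific weighting of the diagonal.

    Off-diagonal:  g_jk = (1/N_jk) Σ_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))
    Diagonal:      g_jj = 1 + (1/N_j) Σ_i (x_ij² - (1+2p_i)x_ij + 2p_i²) / (2p_i(1-p_i))

    Sums run over SNPs non-missing for the pair (or individual); monomorphic
    SNPs are skipped.  Frequencies default to the sample allele frequencies.
    """
    x = panel.genotypes.astype(float)
    obs = panel.genotypes != MISSING
    with np.errstate(invalid="ignore"):
        p = freqs.astype(float) if freqs is not None else (
            np.where(obs, x, 0.0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        )
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic (or unobserved); GRM undefined")
    xp = x[:, poly]
    op = obs[:, poly]
    pp = p[poly]
    het = 2.0 * pp * (1.0 - pp)

    # off-diagonal: pairwise-complete standardized cross-products
    z = np.where(op, (xp - 2.0 * pp) / np.sqrt(het), 0.0)
    n_pair = op.astype(np.float64) @ op.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (z @ z.T) / n_pair

    # diagonal: Yang's within-individual term
    diag_terms = np.where(op, (xp * xp - (1.0 + 2.0 * pp) * xp + 2.0 * pp * pp) / het, 0.0)
    n_ind = op.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fgrm = diag_terms.sum(axis=1) / n_ind
    np.fill_diagonal(g, 1.0 + fgrm)

    freqs_out = np.where(poly, p, np.nan)
    return GenomicRelationshipResult(
        ids=list(panel.ids),
        g=g,
        fgrm=fgrm,
        freqs=freqs_out,
        n_snps_used=int(poly.sum()),
    )


def fgrm_summary(res: GenomicRelationshipResult) -> dict:
    """Mean/SD/min/max of FGRM, in percent."""
    v = 100.0 * res.fgrm
    return {
        "mean_pct": float(np.mean(v)),
        "sd_pct": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "min_pct": float(np.min(v)),
        "max_pct": float(np.max(v)),
        "n": int(v.size),
    }


def export_grm(res: GenomicRelationshipResult, square_path=None, triplet_path=None) -> None:
    """Write the GRM as a square text matrix and/or (id1, id2, value) triplets."""
    if square_path is not None:
        pd.DataFrame(res.g, index=res.ids, columns=res.ids).to_csv(square_path)
    if triplet_path is not None:
        with open(triplet_path, "w") as fh:
            fh.write("id1\tid2\tvalue\n")
            for j in range(len(res.ids)):
                for k in range(j + 1):
                    fh.write(f"{res.ids[j]}\t{res.ids[k]}\t{res.g[j, k]:.8g}\n")
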