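"""Runs of homozygosity: sliding-window detection, FROH summaries,
length-class tables, per-SNP incidence and ROH islands.

Detection follows the consecutive sliding-window scheme: a fixed-size SNP
window slides one SNP at a time; a SNP joins a run when the fraction of
overlapping windows that are homozygous exceeds a coverage threshold;
maximal in-run stretches are split at large inter-SNP gaps and then
filtered on SNP count, physical length and SNP density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypePanel

MB = 1_000_000

#: length classes in Mb, half-open lower-inclusive bins
LENGTH_CLASSES = ((1, 2), (2, 4), (4, 8), (8, 16), (16, None))
#: minimum-length thresholds (Mb) for the FROH>x summaries
FROH_THRESHOLDS_MB = (1, 2, 4, 8, 16)


@dataclass
class ROHParams:
    """Detection parameters.

    ``max_bp_per_snp`` expresses the minimum SNP density (1 SNP per 1,000 kb
    by default).  The per-window heterozygote/missing allowances, the window
    coverage threshold and the minimum SNP count per run are config knobs
    with conventional defaults.
    """

    window_snp: int = 20
    max_bp_per_snp: float = 1_000_000.0   # density: >= 1 SNP per this many bp
    max_gap: int = 1_000_000              # bp between consecutive SNPs
    min_length: int = 1_000_000           # bp
    max_het_in_window: int = 0
    max_miss_in_window: int = 1
    min_snp_in_run: int = 15
    window_coverage_threshold: float = 0.05

    def __post_init__(self):
        if self.window_snp < 1 or self.min_length < 1 or self.max_gap < 1:
            raise ValueError("window_snp, min_length and max_gap must be positive")
        if self.max_bp_per_snp <= 0:
            raise ValueError("max_bp_per_snp must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ROHSummary:
    """Per-animal FROH plus chromosome / length-class breakdowns."""

    froh: pd.Series                 # per animal
    froh_chr: pd.DataFrame          # animal x chromosome
    froh_by_min_length: pd.DataFrame  # animal x threshold columns "froh_ge_{t}mb"
    class_table: pd.DataFrame
    l_aut: float                    # bp


def _rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0], np.cumsum(x)))
    return c[w:] - c[:-w]


def _runs_of_true(mask: np.ndarray):
    """Yield (start, end) index pairs (inclusive) of maximal True runs."""
    if not mask.any():
        return
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    yield from zip(starts, ends)


def _filter_candidate(pos: np.ndarray, lo: int, hi: int, params: ROHParams):
    """Split [lo, hi] at gaps > max_gap, then apply SNP-count/length/density
    filters; yields surviving (start_idx, end_idx) pairs."""
    seg_pos = pos[lo : hi + 1]
    gaps = np.diff(seg_pos)
    cut = np.flatnonzero(gaps > params.max_gap)
    bounds = [lo] + [lo + c + 1 for c in cut] + [hi + 1]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        e = b1 - 1
        n_snp = e - b0 + 1
        length = int(pos[e] - pos[b0] + 1)
        if n_snp < params.min_snp_in_run:
            continue
        if length < params.min_length:
            continue
        if length / n_snp > params.max_bp_per_snp:
            continue
        yield b0, e


def detect_roh(panel: GenotypePanel, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH for every animal on every chromosome.

    Returns a DataFrame with columns animal, chrom, start, end, length,
    n_snp (positions 1-based inclusive).  Chromosomes with fewer SNPs than
    the window size are skipped (counted in ``panel.qc_log``).
    """
    params = params or ROHParams()
    w = params.window_snp
    records = []
    skipped = 0
    for chrom, idx in panel.snp_map.groupby("chrom", sort=False).indices.items():
        idx = np.sort(np.asarray(idx))
        pos = panel.snp_map.pos.to_numpy()[idx]
        m = len(idx)
        if m < w:
            skipped += 1
            continue
        geno_chr = panel.genotypes[:, idx]
        n_windows_at = _rolling_sum(np.ones(m), w)  # per window-start; all ones
        # windows containing SNP s: starts in [s-w+1, s] ∩ [0, m-w]
        for ai, animal in enumerate(panel.ids):
            g = geno_chr[ai]
            het = (g == 1).astype(np.int64)
            mis = (g == MISSING).astype(np.int64)
            het_w = _rolling_sum(het, w)
            mis_w = _rolling_sum(mis, w)
            ok_w = (het_w <= params.max_het_in_window) & (
                mis_w <= params.max_miss_in_window
            )
            # per-SNP counts of (homozygous) windows containing the SNP
            ok_cov = _window_coverage(ok_w.astype(np.int64), m, w)
            tot_cov = _window_coverage(np.ones(m - w + 1, dtype=np.int64), m, w)
            frac = ok_cov / tot_cov
            in_run = frac > params.window_coverage_threshold
            for lo, hi in _runs_of_true(in_run):
                for b0, e in _filter_candidate(pos, lo, hi, params):
                    records.append(
                        {
                            "animal": animal,
                            "chrom": chrom,
                            "start": int(pos[b0]),
                            "end": int(pos[e]),
                            "length": int(pos[e] - pos[b0] + 1),
                            "n_snp": int(e - b0 + 1),
                        }
                    )
    panel.qc_log["roh_chromosomes_skipped"] = skipped
    return pd.DataFrame(
        records, columns=["animal", "chrom", "start", "end", "length", "n_snp"]
    )


def _window_coverage(win_vals: np.ndarray, m: int, w: int) -> np.ndarray:
    """For each SNP index s in 0..m-1, sum of win_vals over window starts
    containing s (starts s-w+1..s clipped to the valid range)."""
    c = np.concatenate(([0], np.cumsum(win_vals)))
    s = np.arange(m)
    lo = np.clip(s - w + 1, 0, m - w)
    hi = np.clip(s, 0, m - w)
    return c[hi + 1] - c[lo]


def autosome_lengths(snp_map: pd.DataFrame) -> pd.Series:
    """SNP-covered span per chromosome: last - first position + 1."""
    grp = snp_map.groupby("chrom", sort=False).pos
    return grp.max() - grp.min() + 1


def froh(
    segments: pd.DataFrame, snp_map: pd.DataFrame, animals: list[str]
) -> ROHSummary:
    """FROH at genome, chromosome and minimum-length-threshold levels.

    The autosome length L_AUT is the total SNP-covered span (first-to-last
    SNP per chromosome), which makes FROH = 1 attainable for a fully
    homozygous genome.
    """
    chr_len = autosome_lengths(snp_map)
    l_aut = float(chr_len.sum())
    froh_g = pd.Series(0.0, index=animals, name="froh")
    froh_c = pd.DataFrame(0.0, index=animals, columns=chr_len.index)
    thr_cols = {f"froh_ge_{t}mb": pd.Series(0.0, index=animals) for t in FROH_THRESHOLDS_MB}
    if len(segments):
        per = segments.groupby("animal").length.sum()
        froh_g.loc[per.index] = per / l_aut
        per_chr = segments.groupby(["animal", "chrom"]).length.sum()
        for (a, c), v in per_chr.items():
            froh_c.loc[a, c] = v / chr_len[c]
        for t in FROH_THRESHOLDS_MB:
            sel = segments[segments.length >= t * MB]
            if len(sel):
                per_t = sel.groupby("animal").length.sum()
                thr_cols[f"froh_ge_{t}mb"].loc[per_t.index] = per_t / l_aut
    return ROHSummary(
        froh=froh_g,
        froh_chr=froh_c,
        froh_by_min_length=pd.DataFrame(thr_cols),
        class_table=class_table(segments),
        l_aut=l_aut,
    )


def class_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Counts and mean lengths (Mb, SNP) per ROH length class, plus a total row."""
    rows = []
    lengths = segments.length.to_numpy() if len(segments) else np.array([])
    nsnp = segments.n_snp.to_numpy() if len(segments) else np.array([])
    for lo, hi in LENGTH_CLASSES:
        label = f"{lo}-{hi} Mb" if hi is not None else f">{lo} Mb"
        sel = (lengths >= lo * MB) & (lengths < hi * MB if hi is not None else True)
        rows.append(
            {
                "class": label,
                "count": int(sel.sum()),
                "mean_mb": float(lengths[sel].mean() / MB) if sel.any() else float("nan"),
                "mean_snp": float(nsnp[sel].mean()) if sel.any() else float("nan"),
            }
        )
    rows.append(
        {
            "class": "Total",
            "count": int(len(segments)),
            "mean_mb": float(lengths.mean() / MB) if len(segments) else float("nan"),
            "mean_snp": float(nsnp.mean()) if len(segments) else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def class_total(class_counts) -> int:
    """Total ROH count from per-class counts."""
    return int(np.sum(np.asarray(list(class_counts), dtype=np.int64)))


def class_share_pct(class_count: int, total: int) -> float:
    """Percentage of all ROH in one length class."""
    return 100.0 * class_count / total


@dataclass
class IslandSet:
    """Per-SNP ROH incidence and the above-threshold island intervals."""

    incidence: pd.DataFrame          # snp, chrom, pos, incidence_pct
    islands: pd.DataFrame            # chrom, start, end, n_snp
    threshold_pct: float


def snp_incidence(segments: pd.DataFrame, panel: GenotypePanel) -> np.ndarray:
    """Percentage of animals whose ROH cover each SNP of the panel map."""
    counts = np.zeros(panel.n_snps, dtype=np.int64)
    chrom_arr = panel.snp_map.chrom.to_numpy()
    pos_arr = panel.snp_map.pos.to_numpy()
    for chrom, seg in segments.groupby("chrom", sort=False) if len(segments) else []:
        snp_idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[snp_idx]
        for _, row in seg.iterrows():
            lo = np.searchsorted(pos, row.start, side="left")
            hi = np.searchsorted(pos, row.end, side="right")
            counts[snp_idx[lo:hi]] += 1
    return 100.0 * counts / panel.n_animals


def roh_islands(
    segments: pd.DataFrame, panel: GenotypePanel, threshold_pct: float = 50.0
) -> IslandSet:
    """Islands = maximal stretches of consecutive SNPs whose ROH incidence is
    strictly above the threshold."""
    inc = snp_incidence(segments, panel)
    incidence = panel.snp_map[["snp", "chrom", "pos"]].copy()
    incidence["incidence_pct"] = inc
    rows = []
    for chrom, grp in incidence.groupby("chrom", sort=False):
        above = (grp.incidence_pct > threshold_pct).to_numpy()
        pos = grp.pos.to_numpy()
        for lo, hi in _runs_of_true(above):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[lo]),
                    "end": int(pos[hi]),
                    "n_snp": int(hi - lo + 1),
                }
            )
    islands = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snp"])
    return IslandSet(incidence=incidence, islands=islands, threshold_pct=threshold_pct)


def annotate_islands(islands: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Overlap-join islands against user intervals (columns chrom, start,
    end, name); returns one row per (island, overlapping interval)."""
    rows = []
    for _, isl in islands.iterrows():
        hits = intervals[
            (intervals.chrom.astype(str) == str(isl.chrom))
            & (intervals.start <= isl.end)
            & (intervals.end >= isl.start)
        ]
        if len(hits) == 0:
            rows.append({**isl.to_dict(), "feature": None})
        for _, h in hits.iterrows():
            rows.append({**isl.to_dict(), "feature": h.get("name")})
    return pd.DataFrame(rows)


def segments_to_bed(segments: pd.DataFrame, path, zero_based: bool = True) -> None:
    """Write segments as BED-like TSV (0-based half-open by default)."""
    df = segments.copy()
    if zero_based:
        df["start"] = df["start"] - 1  # end stays: half-open == inclusive end
    df[["chrom", "start", "end", "animal", "n_snp"]].to_csv(
        path, sep="\t", header=False, index=False
    )
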