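import numpy as np
import pandas as pd
import pytest

from pedgen.genotypes import MISSING
from pedgen.roh import (
    MB,
    ROHParams,
    class_share_pct,
    class_table,
    class_total,
    detect_roh,
    froh,
    roh_islands,
    snp_incidence,
)

from conftest import make_panel


def brute_force_roh(panel, params):
    """Independent enumerator: a SNP is in-run iff it lies in at least one
    window of `window_snp` consecutive SNPs with zero heterozygotes and at
    most `max_miss_in_window` missing calls; maximal in-run stretches are
    split at large gaps and filtered like the detector."""
    out = []
    for chrom in panel.snp_map.chrom.unique():
        snp_sel = np.flatnonzero((panel.snp_map.chrom == chrom).to_numpy())
        pos = panel.snp_map.pos.to_numpy()[snp_sel]
        m = len(snp_sel)
        w = params.window_snp
        if m < w:
            continue
        for ai, animal in enumerate(panel.ids):
            g = panel.genotypes[ai, snp_sel]
            in_run = [False] * m
            for start in range(m - w + 1):
                win = g[start : start + w]
                if np.sum(win == 1) == 0 and np.sum(win == MISSING) <= params.max_miss_in_window:
                    for k in range(start, start + w):
                        in_run[k] = True
            # maximal stretches
            s = 0
            while s < m:
                if not in_run[s]:
                    s += 1
                    continue
                e = s
                while e + 1 < m and in_run[e + 1]:
                    e += 1
                # split at gaps
                pieces, piece = [], [s]
                for k in range(s + 1, e + 1):
                    if pos[k] - pos[k - 1] > params.max_gap:
                        pieces.append((piece[0], piece[-1]))
                        piece = [k]
                    else:
                        piece.append(k)
                pieces.append((piece[0], piece[-1]))
                for b, t in pieces:
                    n_snp = t - b + 1
                    length = int(pos[t] - pos[b] + 1)
                    if (
                        n_snp >= params.min_snp_in_run
                        and length >= params.min_length
                        and length / n_snp <= params.max_bp_per_snp
                    ):
                        out.append(
                            {
                                "animal": animal,
                                "chrom": chrom,
                                "start": int(pos[b]),
                                "end": int(pos[t]),
                                "length": length,
                                "n_snp": n_snp,
                            }
                        )
                s = e + 1
    return pd.DataFrame(out, columns=["animal", "chrom", "start", "end", "length", "n_snp"])


ORACLE_PARAMS = ROHParams(
    window_snp=5,
    min_length=100_000,
    max_gap=200_000,
    min_snp_in_run=4,
    max_het_in_window=0,
    max_miss_in_window=1,
    window_coverage_threshold=0.0,
)


def random_small_panel(rng):
    m = int(rng.integers(3, 50))
    n_an = int(rng.integers(1, 4))
    geno = rng.choice([0, 1, 2, 2, 0, 2, 0, MISSING], size=(n_an, m)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 3_000_000, dtype=np.int64), size=m, replace=False))
    return make_panel(geno, pos)


def test_detector_matches_brute_force_randomized():
    rng = np.random.default_rng(77)
    for _ in range(300):
        panel = random_small_panel(rng)
        got = detect_roh(panel, ORACLE_PARAMS).sort_values(
            ["animal", "chrom", "start"]).reset_index(drop=True)
        want = brute_force_roh(panel, ORACLE_PARAMS).sort_values(
            ["animal", "chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)


def test_all_homozygous_single_run():
    pos = (np.arange(30) + 1) * 100_000
    panel = make_panel(np.zeros((1, 30), dtype=np.int8), pos)
    segs = detect_roh(panel, ROHParams())
    assert len(segs) == 1
    seg = segs.iloc[0]
    assert (seg.start, seg.end) == (100_000, 3_000_000)
    assert seg.length == 2_900_001 and seg.n_snp == 30


def test_gap_splits_candidate():
    # 30 hom SNPs spaced 100 kb with a 1.5 Mb jump between SNP 15 and 16
    pos = np.concatenate([
        (np.arange(15) + 1) * 100_000,
        1_500_000 + 1_500_000 + np.arange(15) * 100_000,
    ])
    panel = make_panel(np.zeros((1, 30), dtype=np.int8), pos)
    segs = detect_roh(panel, ROHParams())
    assert len(segs) == 2
    assert segs.length.tolist() == [1_400_001, 1_400_001]


def test_short_run_rejected_by_min_length():
    pos = (np.arange(20) + 1) * 35_000  # span 0.7 Mb, 20 hom SNPs
    panel = make_panel(np.zeros((1, 20), dtype=np.int8), pos)
    segs = detect_roh(panel, ROHParams())
    assert len(segs) == 0


def test_low_density_run_rejected():
    params = ROHParams(window_snp=5, min_snp_in_run=5, max_gap=10 * MB)
    pos = (np.arange(15) + 1) * 2_000_000  # 1 SNP per 2 Mb < required density
    panel = make_panel(np.zeros((1, 15), dtype=np.int8), pos)
    assert len(detect_roh(panel, params)) == 0


def test_heterozygote_breaks_runs():
    pos = (np.arange(41) + 1) * 100_000
    g = np.zeros((1, 41), dtype=np.int8)
    g[0, 20] = 1
    panel = make_panel(g, pos)
    segs = detect_roh(panel, ROHParams(max_het_in_window=0, window_coverage_threshold=0.0))
    assert len(segs) == 2
    assert 2_100_000 not in set(range(int(segs.start.iloc[1]), int(segs.end.iloc[0]) + 1))


def test_small_chromosome_skipped():
    panel = make_panel(np.zeros((1, 5), dtype=np.int8), (np.arange(5) + 1) * 100_000)
    segs = detect_roh(panel, ROHParams(window_snp=20))
    assert len(segs) == 0
    assert panel.qc_log["roh_chromosomes_skipped"] == 1


def _seg(animal, chrom, start, end, n_snp=50):
    return {"animal": animal, "chrom": chrom, "start": start, "end": end,
            "length": end - start + 1, "n_snp": n_snp}


def test_froh_no_roh_zero():
    panel = make_panel(np.ones((2, 25), dtype=np.int8), (np.arange(25) + 1) * 100_000)
    empty = detect_roh(panel, ROHParams())
    summary = froh(empty, panel.snp_map, panel.ids)
    assert (summary.froh == 0).all()


def test_froh_fully_homozygous_is_one():
    pos = (np.arange(30) + 1) * 100_000
    panel = make_panel(np.zeros((1, 30), dtype=np.int8), pos)
    segs = detect_roh(panel, ROHParams())
    summary = froh(segs, panel.snp_map, panel.ids)
    assert summary.froh.iloc[0] == pytest.approx(1.0)
    assert summary.froh_chr.iloc[0, 0] == pytest.approx(1.0)


def test_froh_arithmetic_hand_case():
    # ROH of 1.5, 3, 20 Mb on a 100 Mb autosome
    snp_map = pd.DataFrame({"snp": ["a", "b"], "chrom": ["1", "1"],
                            "pos": [1, 100 * MB], "a1": "A", "a2": "B"})
    segs = pd.DataFrame([
        _seg("x", "1", 1, int(1.5 * MB)),
        _seg("x", "1", 2 * MB, 5 * MB - 1),
        _seg("x", "1", 10 * MB, 30 * MB - 1),
    ])
    summary = froh(segs, snp_map, ["x"])
    assert summary.l_aut == 100 * MB
    assert summary.froh["x"] == pytest.approx(0.245)
    assert summary.froh_by_min_length.loc["x", "froh_ge_4mb"] == pytest.approx(0.20)
    counts = dict(zip(summary.class_table["class"], summary.class_table["count"]))
    assert counts["1-2 Mb"] == 1 and counts["2-4 Mb"] == 1 and counts[">16 Mb"] == 1


def test_froh_monotone_in_threshold():
    rng = np.random.default_rng(13)
    segs = pd.DataFrame([
        _seg(f"an{i}", "1", s, s + int(l))
        for i in range(10)
        for s, l in zip(rng.integers(1, 50 * MB, 5), rng.uniform(1 * MB, 30 * MB, 5))
    ])
    snp_map = pd.DataFrame({"snp": ["a", "b"], "chrom": ["1", "1"],
                            "pos": [1, 100 * MB], "a1": "A", "a2": "B"})
    summary = froh(segs, snp_map, [f"an{i}" for i in range(10)])
    vals = summary.froh_by_min_length.to_numpy()
    assert np.all(np.diff(vals, axis=1) <= 1e-15)


def test_class_table_boundary_two_mb():
    segs = pd.DataFrame([_seg("x", "1", 1, 2 * MB)])  # exactly 2.0 Mb
    tab = class_table(segs)
    counts = dict(zip(tab["class"], tab["count"]))
    assert counts["2-4 Mb"] == 1 and counts["1-2 Mb"] == 0


def test_class_total_and_share():
    counts = [7236, 1444, 453, 268, 111]
    assert class_total(counts) == 9512
    assert round(class_share_pct(7236, 9512)) == 76


def test_segment_constraints_recheck():
    # every reported segment satisfies every parameter, independently re-checked
    rng = np.random.default_rng(99)
    for _ in range(20):
        panel = random_small_panel(rng)
        segs = detect_roh(panel, ORACLE_PARAMS)
        pos_by_chrom = {
            c: panel.snp_map[panel.snp_map.chrom == c].pos.to_numpy()
            for c in panel.snp_map.chrom.unique()
        }
        for _, s in segs.iterrows():
            assert s.length >= ORACLE_PARAMS.min_length
            assert s.n_snp >= ORACLE_PARAMS.min_snp_in_run
            assert s.length / s.n_snp <= ORACLE_PARAMS.max_bp_per_snp
            p = pos_by_chrom[s.chrom]
            inside = p[(p >= s.start) & (p <= s.end)]
            assert len(inside) == s.n_snp
            assert np.all(np.diff(inside) <= ORACLE_PARAMS.max_gap)


def test_incidence_and_island_threshold():
    pos = (np.arange(30) + 1) * 100_000
    geno = np.zeros((4, 30), dtype=np.int8)
    panel = make_panel(geno, pos, ids=[f"a{i}" for i in range(4)])
    segs = pd.DataFrame([
        _seg("a0", "1", 100_000, 3_000_000, 30),
        _seg("a1", "1", 100_000, 3_000_000, 30),
        _seg("a2", "1", 100_000, 1_500_000, 15),
    ])
    inc = snp_incidence(segs, panel)
    assert inc[0] == pytest.approx(75.0)   # 3 of 4 animals
    assert inc[-1] == pytest.approx(50.0)  # exactly 50%
    isl = roh_islands(segs, panel, threshold_pct=50.0)
    assert len(isl.islands) == 1
    island = isl.islands.iloc[0]
    # strictly-above SNPs only: the 50% tail is excluded
    assert island.start == 100_000 and island.end == 1_500_000
    assert island.n_snp == 15


def test_island_from_forced_sweep():
    from pedgen.simulate import SimConfig, gene_drop, simulate_pedigree

    cfg = SimConfig(seed=42, n_founders=12, n_generations=2, offspring_per_mating=2,
                    n_chromosomes=2, snps_per_chromosome=800,
                    chromosome_length=50_000_000,
                    sweep_region=(1, 20_000_000, 30_000_000))
    ped, truth = simulate_pedigree(cfg)
    panel, _ = gene_drop(truth.complete_pedigree, cfg)
    segs = detect_roh(panel, ROHParams())
    isl = roh_islands(segs, panel, threshold_pct=50.0)
    assert len(isl.islands) >= 1
    hit = isl.islands[isl.islands.chrom == "2"]
    assert len(hit) >= 1
    assert (hit.start.min() <= 22_000_000) and (hit.end.max() >= 28_000_000)
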