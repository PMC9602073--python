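import numpy as np
import pandas as pd
import pytest

from pedgen.inbreeding import inbreeding_meuwissen_luo
from pedgen.gene_origin import boichard_marginal_contributions, founder_contributions
from pedgen.pedigree import Pedigree, ReferencePopulation
from pedgen.roh import ROHParams, detect_roh, froh
from pedgen.simulate import (
    SimConfig,
    SimulationError,
    gene_drop,
    simulate_pedigree,
    single_locus_gene_drop,
)


def test_full_sib_line_f_series():
    cfg = SimConfig(seed=1, n_founders=2, n_generations=3, offspring_per_mating=2,
                    mating_scheme="full_sib_line")
    ped, truth = simulate_pedigree(cfg)
    by_year = truth.f.groupby(truth.complete_pedigree.birth_year).mean()
    np.testing.assert_allclose(by_year.to_numpy(), [0.0, 0.0, 0.25, 0.375])


def test_no_missing_parents_round_trip(tmp_path):
    from pedgen.pedigree import load_pedigree

    cfg = SimConfig(seed=2, n_founders=8, n_generations=3, p_missing_parent=0.0)
    ped, truth = simulate_pedigree(cfg)
    path = tmp_path / "ped.csv"
    ped.to_frame().assign(
        sire=lambda d: d.sire.fillna("0"), dam=lambda d: d.dam.fillna("0"),
        birth_year=lambda d: d.birth_year.astype(int),
    ).to_csv(path, index=False)
    back = load_pedigree(path)
    assert set(back.ids) == set(ped.ids)
    f1 = pd.Series(inbreeding_meuwissen_luo(ped), index=ped.ids)
    f2 = pd.Series(inbreeding_meuwissen_luo(back), index=back.ids)
    pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())


def test_missing_parent_erasure_after_truth():
    cfg = SimConfig(seed=3, n_founders=10, n_generations=4, p_missing_parent=0.4)
    ped, truth = simulate_pedigree(cfg)
    assert (ped.sire == -1).sum() > (truth.complete_pedigree.sire == -1).sum()
    # truth F comes from the complete pedigree
    f_complete = inbreeding_meuwissen_luo(truth.complete_pedigree)
    np.testing.assert_allclose(truth.f.to_numpy(), f_complete)


def test_sire_bottleneck_fa_below_fe():
    cfg = SimConfig(seed=4, n_founders=14, n_generations=5, offspring_per_mating=2,
                    mating_scheme="sire_bottleneck")
    ped, truth = simulate_pedigree(cfg)
    cp = truth.complete_pedigree
    last_year = np.nanmax(cp.birth_year)
    ref = ReferencePopulation(
        ids=tuple(np.array(cp.ids)[cp.birth_year == last_year]))
    _, fe = founder_contributions(cp, ref)
    res = boichard_marginal_contributions(cp, ref)
    assert res.fa < fe


def test_infeasible_scheme_errors():
    with pytest.raises((SimulationError, ValueError)):
        simulate_pedigree(SimConfig(seed=5, n_founders=1, n_generations=2))


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="scheme"):
        SimConfig(seed=0, mating_scheme="chaotic")


def test_same_seed_identical_outputs():
    cfg = SimConfig(seed=10, n_founders=8, n_generations=3,
                    n_chromosomes=2, snps_per_chromosome=200)
    ped1, t1 = simulate_pedigree(cfg)
    ped2, t2 = simulate_pedigree(cfg)
    assert ped1.ids == ped2.ids
    pd.testing.assert_series_equal(t1.f, t2.f)
    p1, d1 = gene_drop(t1.complete_pedigree, cfg)
    p2, d2 = gene_drop(t2.complete_pedigree, cfg)
    np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
    pd.testing.assert_series_equal(d1.autozygosity, d2.autozygosity)


def test_selfed_genome_autozygosity_half():
    from pedgen.pedigree import AnimalRecord

    ped = Pedigree.from_records(
        [AnimalRecord("p")] + [AnimalRecord(f"x{i}", sire="p", dam="p") for i in range(60)]
    )
    cfg = SimConfig(seed=6, n_founders=1, n_generations=1,
                    n_chromosomes=4, snps_per_chromosome=50)
    panel, truth = gene_drop(ped, cfg)
    selfed = truth.autozygosity.drop("p")
    se = selfed.std(ddof=1) / np.sqrt(len(selfed))
    assert abs(selfed.mean() - 0.5) < 3 * se


def test_full_sib_cohort_autozygosity_quarter():
    from pedgen.pedigree import AnimalRecord

    recs = [AnimalRecord("m"), AnimalRecord("f"),
            AnimalRecord("s", sire="m", dam="f"), AnimalRecord("d", sire="m", dam="f")]
    recs += [AnimalRecord(f"o{i}", sire="s", dam="d") for i in range(300)]
    ped = Pedigree.from_records(recs)
    cfg = SimConfig(seed=7, n_founders=2, n_generations=1,
                    n_chromosomes=5, snps_per_chromosome=50)
    panel, truth = gene_drop(ped, cfg)
    cohort = truth.autozygosity[[f"o{i}" for i in range(300)]]
    se = cohort.std(ddof=1) / np.sqrt(len(cohort))
    assert abs(cohort.mean() - 0.25) < 3 * se


def test_founder_population_froh_and_fgrm():
    from pedgen.genotypes import GenotypePanel
    from pedgen.grm import build_grm_yang

    cfg = SimConfig(seed=8, n_founders=40, n_generations=1,
                    n_chromosomes=3, snps_per_chromosome=1200)
    ped, truth = simulate_pedigree(cfg)
    panel, dtruth = gene_drop(truth.complete_pedigree, cfg)
    nf = len(truth.complete_pedigree.founders)
    founders = GenotypePanel(ids=panel.ids[:nf], genotypes=panel.genotypes[:nf],
                             snp_map=panel.snp_map)
    assert (dtruth.autozygosity.iloc[:nf] == 0).all()
    segs = detect_roh(founders, ROHParams())
    summary = froh(segs, founders.snp_map, founders.ids)
    assert summary.froh.mean() < 0.01
    res = build_grm_yang(founders, freqs=dtruth.founder_freqs)
    se = res.fgrm.std(ddof=1) / np.sqrt(nf)
    assert abs(res.fgrm.mean()) < 3 * se


def test_gene_drop_requires_complete_pedigree():
    from pedgen.pedigree import AnimalRecord

    ped = Pedigree.from_records(
        [AnimalRecord("a"), AnimalRecord("b", sire="a")]  # one known parent
    )
    with pytest.raises(SimulationError, match="complete"):
        gene_drop(ped, SimConfig(seed=9, n_chromosomes=1, snps_per_chromosome=10))


def test_founder_fractions_match_expected_q():
    cfg = SimConfig(seed=12, n_founders=6, n_generations=3,
                    n_chromosomes=3, snps_per_chromosome=50)
    ped, truth = simulate_pedigree(cfg)
    cp = truth.complete_pedigree
    panel, dtruth = gene_drop(cp, cfg)
    ref_ids = tuple(a for a, y in zip(cp.ids, cp.birth_year) if y == np.nanmax(cp.birth_year))
    q, _ = founder_contributions(cp, ReferencePopulation(ids=ref_ids))
    realized = dtruth.founder_fractions.loc[list(ref_ids)].mean(axis=0)
    for founder, expect in q.items():
        assert realized.get(founder, 0.0) == pytest.approx(expect, abs=0.12)


def test_single_locus_drop_phantom_keys():
    from pedgen.pedigree import AnimalRecord

    ped = Pedigree.from_records(
        [AnimalRecord("f"), AnimalRecord("x", dam="f"),
         AnimalRecord("y", sire="x", dam="f")]
    )
    rng = np.random.default_rng(0)
    freqs = single_locus_gene_drop(ped, ("y",), 2000, rng)
    assert set(freqs) <= {"f", "x#sire"}
    assert sum(freqs.values()) == pytest.approx(1.0)


def test_genotype_missingness_injection():
    cfg = SimConfig(seed=13, n_founders=6, n_generations=2,
                    n_chromosomes=2, snps_per_chromosome=300,
                    p_missing_genotype=0.1)
    ped, truth = simulate_pedigree(cfg)
    panel, _ = gene_drop(truth.complete_pedigree, cfg)
    miss = (panel.genotypes == -1).mean()
    assert 0.05 < miss < 0.15
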