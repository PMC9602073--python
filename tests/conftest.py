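import numpy as np
import pandas as pd
import pytest

from pedgen.pedigree import AnimalRecord, Pedigree, ReferencePopulation


@pytest.fixture
def trio():
    """Two founders and their offspring."""
    return Pedigree.from_records(
        [
            AnimalRecord("1", sex="M", birth_year=2000),
            AnimalRecord("2", sex="F", birth_year=2000),
            AnimalRecord("3", sire="1", dam="2", sex="F", birth_year=2005),
        ]
    )


@pytest.fixture
def bottleneck():
    """Founders 1,2 -> son 3; 3 mated to founder dams 4,5 -> 6,7."""
    return Pedigree.from_records(
        [
            AnimalRecord("1"),
            AnimalRecord("2"),
            AnimalRecord("4"),
            AnimalRecord("5"),
            AnimalRecord("3", sire="1", dam="2"),
            AnimalRecord("6", sire="3", dam="4"),
            AnimalRecord("7", sire="3", dam="5"),
        ]
    )


@pytest.fixture
def bottleneck_ref():
    return ReferencePopulation(ids=("6", "7"))


def make_random_pedigree(rng: np.random.Generator, n: int, p_unknown: float = 0.2) -> Pedigree:
    """Random valid pedigree: parents drawn among earlier animals."""
    recs = []
    for i in range(n):
        sire = dam = None
        if i >= 2 and rng.random() > p_unknown:
            sire = str(int(rng.integers(i)) + 1)
        if i >= 2 and rng.random() > p_unknown:
            dam = str(int(rng.integers(i)) + 1)
            if dam == sire:
                dam = None
        recs.append(
            AnimalRecord(
                str(i + 1),
                sire=sire,
                dam=dam,
                sex="M" if rng.random() < 0.5 else "F",
                birth_year=2000 + i // 5,
            )
        )
    return Pedigree.from_records(recs)


def full_sib_line(generations: int) -> Pedigree:
    """Repeated brother x sister matings starting from unrelated founders."""
    recs = [AnimalRecord("m0", sex="M"), AnimalRecord("f0", sex="F")]
    for g in range(1, generations + 1):
        s, d = f"m{g - 1}", f"f{g - 1}"
        recs.append(AnimalRecord(f"m{g}", sire=s, dam=d, sex="M"))
        recs.append(AnimalRecord(f"f{g}", sire=s, dam=d, sex="F"))
    return Pedigree.from_records(recs)


def make_panel(genotypes, positions, chrom="1", ids=None):
    """Build a GenotypePanel from a genotype matrix and SNP positions."""
    from pedgen.genotypes import GenotypePanel

    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.ndim == 1:
        genotypes = genotypes[None, :]
    m = genotypes.shape[1]
    if np.isscalar(chrom):
        chrom = [str(chrom)] * m
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "chrom": [str(c) for c in chrom],
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "B",
        }
    )
    ids = ids or [f"an{i}" for i in range(genotypes.shape[0])]
    return GenotypePanel(ids=list(ids), genotypes=genotypes, snp_map=snp_map)
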