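"""Synthetic pedigrees and gene-dropped genotype panels with known ground
truth.

Founders carry two uniquely labeled haplotypes; transmission applies
crossovers as a Poisson process (Haldane, no interference) on a uniform
genetic map.  Realized autozygosity — the fraction of the diploid genome
where both haplotypes descend from the same founder haplotype — provides
the truth against which pedigree F and FROH are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inbreeding import inbreeding_meuwissen_luo
from .genotypes import MISSING, GenotypePanel
from .pedigree import UNKNOWN, AnimalRecord, Pedigree

MATING_SCHEMES = ("random", "circular", "full_sib_line", "sire_bottleneck")


@dataclass
class SimConfig:
    """Simulation parameters; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_founders: int = 20
    n_generations: int = 5
    offspring_per_mating: int = 2
    mating_scheme: str = "random"
    p_missing_parent: float = 0.0
    birth_year_start: int = 1956
    year_spacing: int = 5
    n_chromosomes: int = 5
    snps_per_chromosome: int = 500
    chromosome_length: int = 100_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    recomb_rate_cm_per_mb: float = 1.0
    p_missing_genotype: float = 0.0
    #: optional (chromosome index, start bp, end bp): founder alleles are made
    #: identical there, forcing a shared homozygous haplotype (sweep analog)
    sweep_region: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.mating_scheme not in MATING_SCHEMES:
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")
        if min(self.n_founders, self.n_generations, self.offspring_per_mating,
               self.n_chromosomes, self.snps_per_chromosome) < 1:
            raise ValueError("all counts must be >= 1")
        for p in (self.p_missing_parent, self.p_missing_genotype):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth recorded before any information is discarded."""

    complete_pedigree: Pedigree
    f: pd.Series                      # pedigree F from the complete pedigree
    autozygosity: pd.Series | None = None  # realized IBD fraction per animal
    founder_fractions: pd.DataFrame | None = None  # animal x founder genome shares
    founder_freqs: np.ndarray | None = None  # per-SNP Bernoulli allele frequency used


class SimulationError(ValueError):
    pass


def _sexes(n: int, rng: np.random.Generator) -> list[str]:
    """Random sexes with both sexes guaranteed when n >= 2."""
    sex = ["M" if rng.random() < 0.5 else "F" for _ in range(n)]
    if n >= 2:
        if "M" not in sex:
            sex[0] = "M"
        if "F" not in sex:
            sex[-1] = "F"
    return sex


def simulate_pedigree(cfg: SimConfig) -> tuple[Pedigree, TruthSet]:
    """Discrete-generation pedigree under the configured mating scheme.

    Truth F is computed on the complete pedigree; parent links are erased at
    rate ``p_missing_parent`` only afterwards, on the returned copy.
    """
    rng = np.random.default_rng(cfg.seed)
    recs: list[AnimalRecord] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"A{counter:05d}"

    year0 = cfg.birth_year_start
    founders = []
    sexes = _sexes(cfg.n_founders, rng)
    for k in range(cfg.n_founders):
        a = new_id()
        founders.append((a, sexes[k]))
        recs.append(AnimalRecord(id=a, sex=sexes[k], birth_year=year0))
    current = founders
    for g in range(1, cfg.n_generations + 1):
        males = [a for a, s in current if s == "M"]
        females = [a for a, s in current if s == "F"]
        if not males or not females:
            raise SimulationError(
                f"scheme {cfg.mating_scheme!r} infeasible: generation {g - 1} "
                f"has {len(males)} males and {len(females)} females"
            )
        matings: list[tuple[str, str]] = []
        if cfg.mating_scheme == "random":
            for dam in females:
                matings.append((males[rng.integers(len(males))], dam))
        elif cfg.mating_scheme == "circular":
            for i, dam in enumerate(sorted(females)):
                matings.append((sorted(males)[(i + 1) % len(males)], dam))
        elif cfg.mating_scheme == "full_sib_line":
            if cfg.offspring_per_mating < 2:
                raise SimulationError("full_sib_line needs offspring_per_mating >= 2")
            matings.append((males[0], females[0]))
        elif cfg.mating_scheme == "sire_bottleneck":
            sire = males[rng.integers(len(males))]
            for dam in females:
                matings.append((sire, dam))
        offspring: list[tuple[str, str]] = []
        year = year0 + g * cfg.year_spacing
        for sire, dam in matings:
            n_off = cfg.offspring_per_mating
            off_sex = _sexes(n_off, rng)
            for k in range(n_off):
                a = new_id()
                offspring.append((a, off_sex[k]))
                recs.append(
                    AnimalRecord(id=a, sire=sire, dam=dam, sex=off_sex[k], birth_year=year)
                )
        current = offspring

    complete = Pedigree.from_records(recs)
    f = pd.Series(inbreeding_meuwissen_luo(complete), index=complete.ids, name="f")
    truth = TruthSet(complete_pedigree=complete, f=f)

    if cfg.p_missing_parent > 0:
        erased = []
        for rec in recs:
            sire = rec.sire if rec.sire is None or rng.random() >= cfg.p_missing_parent else None
            dam = rec.dam if rec.dam is None or rng.random() >= cfg.p_missing_parent else None
            erased.append(AnimalRecord(rec.id, sire, dam, rec.sex, rec.birth_year))
        return Pedigree.from_records(erased), truth
    return complete, truth


# ---------------------------------------------------------------------------
# gene dropping with recombination
# ---------------------------------------------------------------------------

Haplotype = tuple[np.ndarray, np.ndarray]  # (internal breakpoints bp, segment labels)


def _slice_hap(hap: Haplotype, a: float, b: float) -> tuple[list[float], list[int]]:
    """Segments of ``hap`` restricted to [a, b): internal breaks and labels."""
    breaks, labels = hap
    lo = int(np.searchsorted(breaks, a, side="right"))
    hi = int(np.searchsorted(breaks, b, side="left"))
    return list(breaks[lo:hi]), list(labels[lo : hi + 1])


def _meiosis(pair: tuple[Haplotype, Haplotype], length: float,
             rate_per_bp: float, rng: np.random.Generator) -> Haplotype:
    """One gamete: Poisson crossovers, uniform positions, random start phase."""
    k = rng.poisson(length * rate_per_bp)
    cur = int(rng.integers(2))
    if k == 0:
        breaks, labels = pair[cur]
        return breaks.copy(), labels.copy()
    xs = np.sort(rng.uniform(0.0, length, size=k))
    bounds = np.concatenate(([0.0], xs, [length]))
    raw_breaks: list[float] = []  # left boundary of each raw segment
    raw_labels: list[int] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if b > a:
            sb, sl = _slice_hap(pair[cur], a, b)
            for j, lab in enumerate(sl):
                raw_breaks.append(a if j == 0 else sb[j - 1])
                raw_labels.append(lab)
        cur ^= 1
    # compress adjacent segments carrying the same label
    breaks: list[float] = []
    labels: list[int] = [raw_labels[0]]
    for j in range(1, len(raw_labels)):
        if raw_labels[j] != labels[-1]:
            breaks.append(raw_breaks[j])
            labels.append(raw_labels[j])
    return np.asarray(breaks, dtype=float), np.asarray(labels, dtype=np.int64)


def _hap_labels_at(hap: Haplotype, pos: np.ndarray) -> np.ndarray:
    breaks, labels = hap
    return labels[np.searchsorted(breaks, pos, side="right")]


def _shared_length(h1: Haplotype, h2: Haplotype, length: float) -> float:
    """Total length where both haplotypes carry the same founder label."""
    cuts = np.unique(np.concatenate((h1[0], h2[0], [0.0, length])))
    mids = (cuts[:-1] + cuts[1:]) / 2.0
    same = _hap_labels_at(h1, mids) == _hap_labels_at(h2, mids)
    return float(np.sum((cuts[1:] - cuts[:-1])[same]))


def gene_drop(ped: Pedigree, cfg: SimConfig,
              rng: np.random.Generator | None = None) -> tuple[GenotypePanel, TruthSet]:
    """Drop labeled founder haplotypes through a complete pedigree.

    Requires every non-founder to have both parents recorded.  Returns the
    0/1/2 genotype panel (with optional missingness) and the truth set with
    realized per-animal autozygosity and founder genome fractions.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = ped.n
    for i in range(n):
        known = int(ped.sire[i] != UNKNOWN) + int(ped.dam[i] != UNKNOWN)
        if known == 1:
            raise SimulationError(
                f"gene_drop needs a complete pedigree; {ped.ids[i]} has one known parent"
            )
    founder_idx = {int(i): k for k, i in enumerate(np.flatnonzero(ped.is_founder))}
    n_f = len(founder_idx)
    rate = cfg.recomb_rate_cm_per_mb * 1e-8  # Morgans per bp
    L = float(cfg.chromosome_length)
    genome = L * cfg.n_chromosomes

    # SNP map: sorted unique positions per chromosome
    pos_by_chr = []
    map_rows = []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(
            rng.choice(cfg.chromosome_length - 1, size=cfg.snps_per_chromosome,
                       replace=False).astype(np.int64) + 1
        )
        pos_by_chr.append(pos)
        for j, p in enumerate(pos):
            map_rows.append({"snp": f"snp{c + 1}_{j + 1}", "chrom": str(c + 1),
                            "pos": int(p), "a1": "A", "a2": "B"})
    snp_map = pd.DataFrame(map_rows)

    # founder haplotype alleles: Bernoulli(maf) per SNP, maf ~ U(low, high)
    hap_alleles = []
    maf_by_chr = []
    for c in range(cfg.n_chromosomes):
        maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.snps_per_chromosome)
        alle = (rng.random((2 * n_f, cfg.snps_per_chromosome)) < maf).astype(np.int8)
        hap_alleles.append(alle)
        maf_by_chr.append(maf)
    if cfg.sweep_region is not None:
        c, lo, hi = cfg.sweep_region
        sel = (pos_by_chr[c] >= lo) & (pos_by_chr[c] <= hi)
        hap_alleles[c][:, sel] = 1

    # drop haplotypes chromosome by chromosome
    haps: list[list[tuple[Haplotype, Haplotype]]] = [[None] * n for _ in range(cfg.n_chromosomes)]
    empty = np.empty(0, dtype=float)
    for c in range(cfg.n_chromosomes):
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN:
                k = founder_idx[int(i)]
                haps[c][i] = (
                    (empty.copy(), np.array([2 * k], dtype=np.int64)),
                    (empty.copy(), np.array([2 * k + 1], dtype=np.int64)),
                )
            else:
                haps[c][i] = (
                    _meiosis(haps[c][s], L, rate, rng),
                    _meiosis(haps[c][d], L, rate, rng),
                )

    # realized autozygosity and founder genome fractions
    auto = np.zeros(n)
    frac = np.zeros((n, n_f))
    for c in range(cfg.n_chromosomes):
        for i in range(n):
            h1, h2 = haps[c][i]
            auto[i] += _shared_length(h1, h2, L)
            for h in (h1, h2):
                breaks, labels = h
                edges = np.concatenate(([0.0], breaks, [L]))
                seg_len = edges[1:] - edges[:-1]
                np.add.at(frac[i], labels // 2, seg_len)
    auto /= genome
    frac /= 2.0 * genome

    # genotypes
    geno = np.empty((n, cfg.n_chromosomes * cfg.snps_per_chromosome), dtype=np.int8)
    for c in range(cfg.n_chromosomes):
        sl = slice(c * cfg.snps_per_chromosome, (c + 1) * cfg.snps_per_chromosome)
        pos = pos_by_chr[c].astype(float)
        col = np.arange(cfg.snps_per_chromosome)
        for i in range(n):
            h1, h2 = haps[c][i]
            a1 = hap_alleles[c][_hap_labels_at(h1, pos), col]
            a2 = hap_alleles[c][_hap_labels_at(h2, pos), col]
            geno[i, sl] = a1 + a2
    if cfg.p_missing_genotype > 0:
        mask = rng.random(geno.shape) < cfg.p_missing_genotype
        geno[mask] = MISSING

    panel = GenotypePanel(ids=list(ped.ids), genotypes=geno, snp_map=snp_map)
    f = pd.Series(inbreeding_meuwissen_luo(ped), index=ped.ids, name="f")
    founder_ids = [ped.ids[i] for i in sorted(founder_idx, key=founder_idx.get)]
    truth = TruthSet(
        complete_pedigree=ped,
        f=f,
        autozygosity=pd.Series(auto, index=ped.ids, name="autozygosity"),
        founder_fractions=pd.DataFrame(frac, index=ped.ids, columns=founder_ids),
        founder_freqs=np.concatenate(maf_by_chr),
    )
    return panel, truth


def single_locus_gene_drop(
    ped: Pedigree, ref_ids, n_reps: int, rng: np.random.Generator
) -> dict[str, float]:
    """Monte-Carlo founder-origin frequencies at a single unlinked locus.

    Each founder contributes its own origin code; an unknown parent slot of
    a non-founder contributes a phantom code ``"<id>#sire"``/``"<id>#dam"``.
    Returns the mean fraction of reference-population gene copies per origin,
    keyed like :func:`pedgen.gene_origin.founder_contributions`.
    """
    n = ped.n
    code_of: dict[str, int] = {}

    def get_code(name: str) -> int:
        if name not in code_of:
            code_of[name] = len(code_of)
        return code_of[name]

    origin = np.empty((n, 2, n_reps), dtype=np.int32)
    founder = ped.is_founder
    reps = np.arange(n_reps)
    for i in range(n):
        if founder[i]:
            origin[i, :, :] = get_code(ped.ids[i])
            continue
        for slot, (parent, side) in enumerate(
            ((ped.sire[i], "sire"), (ped.dam[i], "dam"))
        ):
            if parent == UNKNOWN:
                origin[i, slot, :] = get_code(f"{ped.ids[i]}#{side}")
            else:
                pick = rng.integers(2, size=n_reps)
                origin[i, slot, :] = origin[parent, pick, reps]
    ref_rows = [ped.index_of(a) for a in ref_ids]
    pool = origin[ref_rows].reshape(-1, n_reps)  # (2*|ref|, reps)
    total = pool.shape[0] * n_reps
    names = {v: k for k, v in code_of.items()}
    vals, counts = np.unique(pool, return_counts=True)
    return {names[int(v)]: cnt / total for v, cnt in zip(vals, counts)}
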