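"""SNP genotype panels: PLINK text (PED/MAP) and binary (BED/BIM/FAM) IO
plus the call-rate / autosome quality control.

Genotypes are coded as the count of the A1 allele {0, 1, 2}; -1 marks a
missing call.  A1/A2 follow the BIM file for binary input; for text PED
input A1 is the lexicographically first observed allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit PLINK codes -> A1 allele count (01 = missing)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """Animal × SNP genotype matrix with its map.

    Attributes
    ----------
    ids : list of str
        Animal ids (FAM/PED order).
    genotypes : ndarray of int8, shape (n_animals, n_snps)
        A1 allele counts; -1 = missing.
    snp_map : DataFrame with columns snp, chrom, pos, a1, a2
    qc_log : dict
        Counts removed per filter (populated by :func:`apply_qc`).
    """

    ids: list[str]
    genotypes: np.ndarray
    snp_map: pd.DataFrame
    qc_log: dict = field(default_factory=dict)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def __post_init__(self):
        if self.genotypes.shape != (len(self.ids), len(self.snp_map)):
            raise GenotypeError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.ids)} animals x {len(self.snp_map)} snps"
            )


def _read_map(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str, "snp": str},
    )
    return df


def read_ped_map(ped_path, map_path) -> GenotypePanel:
    """Read PLINK 1.x text PED/MAP.

    Non-biallelic SNPs are dropped (logged in ``qc_log["non_biallelic"]``);
    a half-missing genotype call is treated as fully missing.
    """
    snp_map = _read_map(map_path)
    m = len(snp_map)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise GenotypeError(
                    f"PED row for {tok[1] if len(tok) > 1 else '?'} has "
                    f"{len(tok) - 6} allele fields, expected {2 * m}"
                )
            ids.append(tok[1])
            allele_rows.append(list(zip(tok[6::2], tok[7::2])))
    # determine alleles per SNP
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    bad = np.zeros(m, dtype=bool)
    for j in range(m):
        seen = sorted({a for row in allele_rows for a in row[j] if a != "0"})
        if len(seen) > 2:
            bad[j] = True
            continue
        a1[j] = seen[0] if seen else "0"
        a2[j] = seen[1] if len(seen) > 1 else "0"
    geno = np.full((len(ids), m), MISSING, dtype=np.int8)
    for i, row in enumerate(allele_rows):
        for j in range(m):
            if bad[j]:
                continue
            x, y = row[j]
            if x == "0" or y == "0":
                continue
            geno[i, j] = (x == a1[j]) + (y == a1[j])
    snp_map = snp_map.assign(a1=a1, a2=a2)
    keep = ~bad
    panel = GenotypePanel(
        ids=ids,
        genotypes=np.ascontiguousarray(geno[:, keep]),
        snp_map=snp_map.loc[keep, ["snp", "chrom", "pos", "a1", "a2"]].reset_index(drop=True),
    )
    panel.qc_log["non_biallelic"] = int(bad.sum())
    return panel


def read_bed(prefix) -> GenotypePanel:
    """Read PLINK binary BED/BIM/FAM (SNP-major)."""
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    ids = fam[1].tolist()
    n, m = len(ids), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != BED_MAGIC:
        raise GenotypeError("not a SNP-major PLINK BED file (bad magic bytes)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise GenotypeError(
            f"BED payload {body.size} bytes, expected {m * bytes_per_snp}"
        )
    body = body.reshape(m, bytes_per_snp)
    # expand each byte into 4 two-bit codes (little-endian within the byte)
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    geno = _BED_DECODE[codes].T  # (n, m)
    return GenotypePanel(
        ids=ids,
        genotypes=np.ascontiguousarray(geno),
        snp_map=bim[["snp", "chrom", "pos", "a1", "a2"]].copy(),
    )


def write_bed(panel: GenotypePanel, prefix) -> None:
    """Write the panel as PLINK binary BED/BIM/FAM."""
    prefix = str(prefix)
    n, m = panel.n_animals, panel.n_snps
    with open(prefix + ".fam", "w") as fh:
        for a in panel.ids:
            fh.write(f"{a} {a} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for _, r in panel.snp_map.iterrows():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{int(r.pos)}\t{r.a1}\t{r.a2}\n")
    bytes_per_snp = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)
    for g, code in _BED_ENCODE.items():
        lut[g & 0xFF] = code
    out = bytearray(BED_MAGIC)
    geno = panel.genotypes.T  # SNP-major
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = lut[geno.astype(np.int16) & 0xFF]
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    out += packed.tobytes()
    Path(prefix + ".bed").write_bytes(bytes(out))


def write_ped_map(panel: GenotypePanel, prefix) -> None:
    """Write the panel as PLINK text PED/MAP."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for _, r in panel.snp_map.iterrows():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{int(r.pos)}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, a in enumerate(panel.ids):
            fields = [a, a, "0", "0", "0", "-9"]
            for j in range(panel.n_snps):
                g = panel.genotypes[i, j]
                a1 = panel.snp_map.a1.iloc[j]
                a2 = panel.snp_map.a2.iloc[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [a1, a1]
                elif g == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


def read_genotypes(path) -> GenotypePanel:
    """Read genotypes from a PLINK prefix or file path (text or binary)."""
    p = str(path)
    for suffix in (".bed", ".bim", ".fam", ".ped", ".map"):
        if p.endswith(suffix):
            p = p[: -len(suffix)]
            break
    if Path(p + ".bed").exists():
        return read_bed(p)
    if Path(p + ".ped").exists():
        return read_ped_map(p + ".ped", p + ".map")
    raise FileNotFoundError(f"no PLINK files found at prefix {p!r}")


def _autosome_mask(chrom: pd.Series, autosomes) -> np.ndarray:
    allowed = {str(c) for c in autosomes}
    return chrom.astype(str).isin(allowed).to_numpy()


def apply_qc(
    panel: GenotypePanel,
    snp_call_rate: float = 0.90,
    animal_call_rate: float = 0.90,
    autosomes=range(1, 30),
) -> GenotypePanel:
    """Quality control: autosomes only, then SNP call rate, then animal call rate.

    SNPs on non-autosomal or unmapped chromosomes are removed first, then
    SNPs below ``snp_call_rate``, then animals below ``animal_call_rate``.
    There is deliberately NO minor-allele-frequency filter: monomorphic and
    rare SNPs are retained so homozygosity is measured correctly.
    """
    log: dict = dict(panel.qc_log)
    log["n_snps_raw"] = panel.n_snps
    log["n_animals_raw"] = panel.n_animals

    auto = _autosome_mask(panel.snp_map.chrom, autosomes)
    log["snps_non_autosomal"] = int((~auto).sum())
    geno = panel.genotypes[:, auto]
    snp_map = panel.snp_map.loc[auto].reset_index(drop=True)

    called = geno != MISSING
    snp_cr = called.mean(axis=0) if geno.shape[0] else np.zeros(geno.shape[1])
    keep_snp = snp_cr >= snp_call_rate
    log["snps_low_call_rate"] = int((~keep_snp).sum())
    geno = geno[:, keep_snp]
    snp_map = snp_map.loc[keep_snp].reset_index(drop=True)

    called = geno != MISSING
    an_cr = called.mean(axis=1) if geno.shape[1] else np.zeros(geno.shape[0])
    keep_an = an_cr >= animal_call_rate
    log["animals_low_call_rate"] = int((~keep_an).sum())
    geno = geno[keep_an, :]
    ids = [a for a, k in zip(panel.ids, keep_an) if k]

    if geno.size == 0:
        raise GenotypeError("no genotypes left after quality control")

    # sort by (chromosome, position); chromosomes numerically when possible
    key = snp_map.assign(
        _c=pd.to_numeric(snp_map.chrom, errors="coerce"), _i=np.arange(len(snp_map))
    ).sort_values(["_c", "chrom", "pos", "_i"], kind="stable")
    order = key._i.to_numpy()
    geno = geno[:, order]
    snp_map = snp_map.iloc[order].reset_index(drop=True)

    log["n_snps_kept"] = geno.shape[1]
    log["n_animals_kept"] = geno.shape[0]
    return GenotypePanel(
        ids=ids, genotypes=np.ascontiguousarray(geno), snp_map=snp_map, qc_log=log
    )
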