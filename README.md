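# pedgen

Pedigree and genomic diversity analysis for livestock populations:

- **Pedigree inbreeding** via Meuwissen–Luo ancestor tracing (linear memory),
  with a dense tabular-method relationship matrix kept as an independent oracle.
- **Average relatedness** (exact row sums of the relationship matrix without
  materializing it), individual rates of inbreeding
  ΔF = 1 − (1 − F)^(1/(EqG − 1)) and realized effective population size
  Ne = 1/(2·mean ΔF).
- **Pedigree depth**: equivalent complete generations, maximum/complete
  generations traced, per-depth completeness index (harmonic mean of the
  sire- and dam-line completeness), and generation intervals along the four
  selection paths (sire–sire, sire–dam, dam–sire, dam–dam).
- **Probability of gene origin**: founder contributions and the effective
  number of founders (1/Σq²), greedy marginal ancestor contributions and the
  effective number of ancestors (1/Σp²), and the number of ancestors
  explaining half the gene pool.
- **Genotypes**: PLINK text (PED/MAP) and binary (BED/BIM/FAM) IO, call-rate
  and autosome quality control (deliberately no MAF filter).
- **Genomic inbreeding**: Yang-estimator GRM with SNP-specific diagonal
  weighting (FGRM = diag(G) − 1), pairwise-complete missing handling.
- **Runs of homozygosity**: consecutive sliding-window detection with
  gap/length/density filters, FROH at genome / chromosome / length-threshold
  level, ROH length-class tables, per-SNP incidence and ROH islands
  (incidence strictly above a population threshold).
- **Estimator comparison**: Pearson correlations with t-based two-sided
  p-values and significance stars.
- **Simulator**: discrete-generation pedigrees under several mating schemes
  and gene dropping of labeled founder haplotypes with Poisson crossovers,
  yielding realized autozygosity and founder-origin ground truth.

## CLI

```bash
# simulate a pedigree + gene-dropped genotypes with ground truth
pedgen simulate --seed 1 --out sim/ --founders 20 --generations 5

# pedigree analysis (F, AR, ΔF/Ne, depth metrics, gene origin, intervals)
pedgen pedigree --pedigree sim/pedigree.csv --reference ref_ids.txt --out out/ped

# genomic analysis (QC, FGRM, ROH/FROH, islands, estimator correlations)
pedgen genomic --genotypes sim/genotypes --pedigree sim/pedigree.csv --out out/gen

# both at once
pedgen all --pedigree sim/pedigree.csv --genotypes sim/genotypes --out out/all
```

Pedigree files are CSV or whitespace tables with columns
`id,sire,dam[,sex,birth_year]`; `0` (configurable) marks an unknown parent.
Genotypes are PLINK prefixes (`.ped/.map` or `.bed/.bim/.fam`). Every output
directory contains a `provenance.json` with the full parameter set.

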