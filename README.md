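# cpsim

Simulation of a two-part recurrent-selection breeding program for inbred
crops, comparing three ways of choosing crossing pairs:

- **GS** — truncation selection on genomic estimated breeding values
  (GEBVs) with random pairing of the top individuals;
- **OCS** — optimal cross selection: maximize the summed mean GEBV of the
  chosen crosses subject to a scheduled genetic-diversity floor, solved
  with an evolutionary search;
- **CPS** — cross potential selection: maximize the summed usefulness
  criterion of each cross's *future inbred* (7x-selfed) progeny,
  `UC = mu + i * h * sigma`, solved exactly as an integer program.

The package contains:

- a phased-genome engine (`cpsim.genome`): Haldane linkage maps,
  no-interference meiosis, crossing, and single-seed-descent selfing;
- synthetic founder panels with block LD and subpopulation structure,
  marker MAF/LD filtering, per-replicate marker subsampling, k-means
  founder choice and the 4-way initial population (`cpsim.founders`);
- additive trait simulation with heritability-controlled phenotypes
  (`cpsim.traits`) and single-kernel G-BLUP with an exact marker-effect
  back-solve (`cpsim.gp`);
- an **exact inbred-progeny moment engine** (`cpsim.progeny`): for every
  within-chromosome marker pair the diplotype of a selfed lineage is a
  16-state Markov chain; the engine reduces all pair covariances to
  quadratic forms and returns the mean and variance of the inbred progeny
  of any cross (or selfing) without simulation.  A gamete-dropping
  Monte-Carlo oracle is included for verification;
- the three selection strategies plus the shared advancement rule
  (`cpsim.selection`), and the 60-cycle program orchestrator with all
  evaluation metrics and matched-replicate aggregation (`cpsim.program`);
- phased VCF / TSV genotype IO, strict YAML configs, tidy result TSVs
  (`cpsim.io`) and a CLI (`cpsim.cli`).

## CLI

```sh
cpsim make-founders --accessions 198 --chroms 20 --snps-per-chrom 200 \
    --maf 0.1 --seed 1 --out founders.tsv

cpsim simulate --config run.yaml --out results/       # one full program
cpsim replicates --config run.yaml --n 20 --out agg/  # matched replicates
cpsim select-crosses --strategy cps --genotypes founders.tsv \
    --effects effects.tsv --out plan.tsv
cpsim progeny-var --genotypes founders.tsv --effects effects.tsv --out uc.tsv
```

`run.yaml` holds `ProgramConfig` keys (unknown keys are rejected), e.g.

```yaml
strategy: cps
h2: 0.6
n_cycles: 60
seed: 1
```

Defaults are the full-scale design: 20 chromosomes x 200 SNPs, 1,000
causal loci with effect variance 0.35, 150 individuals from a 4-way
cross, 10 crosses x 15 progeny per cycle with each parent used at most
twice, 2 individuals advanced per year through 7 rounds of selfing
(50 lines each), and the diversity schedule `t* = 60`, `s = 1`,
`He* = 0.01 He0` for OCS.

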