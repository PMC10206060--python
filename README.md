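# crosspred

Optimal cross selection (OCS) for inbred crop breeding programs.

Choosing which bi-parental crosses to make is among the most consequential
decisions in a breeding program: with 100 candidate parents there are 4,950
possible crosses, population development takes years, and a poor cross burns
resources long before yield can be evaluated. `crosspred` lets a breeder
score every candidate cross *before* making it, from parental SNP genotypes
and historical trial data:

1. **Simulate the progeny a cross would produce.**  F5-derived recombinant
   inbred lines (RILs) are generated by single seed descent on a genetic
   map, with crossovers following the no-interference (Haldane) model —
   Poisson crossover counts per chromosome, uniform positions.
2. **Predict each progeny's genomic estimated breeding value (GEBV)** with
   a model trained on a phenotyped, genotyped line population: RR-BLUP,
   BayesRR, BayesB, or EGBLUP (genomic BLUP extended with an
   additive×additive epistatic kernel, the Hadamard square `H = G∘G` of the
   additive relationship matrix).
3. **Score the cross with a usefulness criterion.**  Classically
   `UC = μ + i·σ_g`; operationally the mean of the top-`i` fraction of the
   predicted progeny GEBVs.  `i = 0` is the plain progeny mean (MV);
   `i = 0.1` and `i = 0.2` emphasize the upper tail a breeder would advance.
4. **Validate retrospectively.**  For crosses that were actually made,
   prediction accuracy is the Spearman correlation between predicted cross
   values and observed mean progeny performance, under training sets of
   varying relatedness (FTS = all lines; WFS = direct progeny of the
   predicted crosses removed; RTS = the same number of unrelated lines
   removed).

Supporting modules handle marker QC (minor-allele-frequency < 0.06 and
missingness > 20% filters, naive imputation), multi-environment trial
analysis (EM-REML entry BLUPs and entry-mean heritability
`H² = σ²_G/(σ²_G + σ²_GxE/e + σ²_R/(er))`), and a synthetic-data generator
that builds complete, fully seeded breeding scenarios so every stage is
testable without proprietary data.

## Worked example

```bash
crosspred synth --seed 4 --config scenario.yaml --out demo/       # synthetic program
crosspred qc --genotypes demo/genotypes.tsv --out demo/clean.tsv
crosspred fit --model egblup --genotypes demo/clean.tsv \
              --phenotypes demo/blups.tsv --out demo/fit.json
crosspred rank --fit demo/fit.json --genotypes demo/clean.tsv \
               --map demo/map.tsv --crosses demo/crosses.csv \
               --n 500 --criterion mv --seed 11 --out demo/ranking.tsv
```

with `scenario.yaml` containing, e.g.:

```yaml
n_chromosomes: 10
n_markers: 500
n_founders: 20
n_training_lines: 200
n_validation_crosses: 12
progeny_per_cross: 10
h2_target: 0.5
```

A run of the same pipeline through `python scripts/acceptance.py --seed 1
--out results/acceptance.json` printed:

```
scenario: 320 lines x 500 markers, 12 realized crosses
QC: retained 466/500 markers
EGBLUP variance components: additive 52.725, epistatic 31.580, residual 57.057
top-ranked cross: TL0004 x TL0198 (MV -2.408, UC0.1 3.353)
validation accuracy (mean over replicates):
 ts  model  criterion     mean      std  count
FTS EGBLUP        0.0 0.922424 0.032750      5
FTS RRBLUP        0.0 0.866667 0.046156      5
RTS EGBLUP        0.0 0.910303 0.023629      5
WFS EGBLUP        0.0 0.568485 0.136222      5
...
```

Reading: the ranking table orders candidate crosses by the chosen
usefulness criterion (`mean` is the predicted progeny mean on the entry-
BLUP scale, `uc_0.1` the mean of the top 10% of predicted progeny).  The
validation summary shows the drop in rank accuracy as training-set
relatedness falls (FTS → WFS), the pattern that makes training-set design a
first-order concern when deploying OCS.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates a
seeded synthetic scenario and re-runs the complete pipeline — QC, model
training, cross ranking, replicated FTS/WFS/RTS validation — printing the
summary above and writing its JSON output to `--out`.

## Layout

```
src/crosspred/
  io_qc.py           genotype/map/phenotype I/O, marker filters, imputation
  pheno.py           trial mixed model, entry BLUPs, heritability
  meiosis.py         gamete and single-seed-descent RIL simulation
  models.py          RR-BLUP, BayesRR/BayesB (Gibbs), EGBLUP, GEBV prediction
  ocs.py             cross enumeration, usefulness criteria, ranking
  validation.py      training-set compositions, Spearman accuracy, replication
  synthetic_data.py  fully synthetic breeding scenarios
  cli.py             `crosspred` command-line pipeline
```

See `docs/methods.md` for the modelling assumptions and numerical choices.
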