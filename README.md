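# haplopaint

Population structure and ancestral-origin analysis for inbred SNP panels:
genotype QC, temporal diversity statistics, donor-panel curation with a
resampling null, and in-silico chromosome painting of recipient genomes as
mosaics of geographically defined donor subpopulations.

The package treats each inbred line as a single haploid allele copy
(calls coded `0`/`1`/`NA`). The stages are:

| module | what it does |
| --- | --- |
| `haplopaint.data_model` | `GenotypeMatrix` / `GeneticMap` / `SampleMetadata` types, CSV + VCF I/O, release-period assignment (cuts at 1920/1970 by default) |
| `haplopaint.synthetic_data` | simulators: Balding–Nichols donor subpopulations with within-subpop mating, mosaic recipients with recorded breakpoint truth, Wright–Fisher drift panels of known Ne, two-channel intensity clouds |
| `haplopaint.genotype_qc` | cluster-distance genotype calling, missingness (> 0.5 removed) and MAF (< 0.05 removed) filters, LD-kNN imputation, donor/recipient SNP intersection |
| `haplopaint.popgen_stats` | Nei (1972) distance, neighbour-joining (Newick), haploid Weir–Cockerham Fst, hierarchical AMOVA with permutation tests, PCA |
| `haplopaint.diversity_ld_ne` | 15-SNP sliding-window haplotype heterozygosity (HHe) and effective haplotype number (HAe), pairwise r², 99th-percentile unlinked background LD, decay-curve block size, LD-based Ne (first-order and NeEstimator-compatible Waples mode) |
| `haplopaint.donor_curation` | NJ-tree cluster pruning of a worldwide donor panel and a 100-replicate size-matched random-subset Fst null |
| `haplopaint.painting` | haploid Li–Stephens copying-model HMM: EM-fitted copying proportions (20 steps), stochastic path sampling (100 replicates), per-SNP modal consensus, ancestry roll-ups by cultivar/period/State, cleaner repaints with excluded donor subpops, deviant-region detection |
| `haplopaint.pipeline` + `haplopaint.cli` | declarative end-to-end runs, stamped reproducible tables, figures |

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (HMM exactness
against exhaustive enumeration, mosaic-recovery accuracy, EM monotonicity,
brute-force estimator oracles, LD-Ne parameter recovery, the resampling
null, and planted deviant-region recovery). `tests/oracles.py` contains the
independent brute-force reference implementations.

## CLI

Everything is reachable through one entry point:

```bash
haplopaint simulate --out sim --n-snps 1000 --n-samples 30 --seed 1
haplopaint qc -g sim/recipients.csv --out recipients_qc.csv
haplopaint fst -g sim/donors.csv --metadata sim/metadata.csv --by subpop --out fst.csv
haplopaint amova -g sim/donors.csv --metadata sim/metadata.csv --out amova.json
haplopaint njtree -g sim/donors.csv --metadata sim/metadata.csv --out tree.nwk
haplopaint diversity -g sim/recipients.csv --map sim/map.tsv --out windows.csv
haplopaint ld -g sim/recipients.csv --map sim/map.tsv --out decay.csv
haplopaint ne -g sim/recipients.csv --method waples
haplopaint curate -g sim/donors.csv --metadata sim/metadata.csv --out curated
haplopaint subset-null -g sim/donors.csv --metadata sim/metadata.csv \
    --target-sizes '{"1": 20, "2": 20}' --observed 0.25
haplopaint paint --donors sim/donors.csv --recipients sim/recipients.csv \
    --map sim/map.tsv --metadata sim/metadata.csv \
    --em-steps 20 --replicates 100 --exclude-subpops 11,12,16 --out paint
haplopaint regions --profile paint_profile.csv --map sim/map.tsv \
    --focal-subpop 22 --out regions.tsv
haplopaint run --config config.yaml --out rundir     # full pipeline
haplopaint report --run-dir rundir                   # figures
```

Runs are deterministic for a fixed `--seed`; `--threads` is accepted for
interface compatibility and never changes results. Pipeline tables carry a
`# config_hash=… seed=…` stamp and re-running the same config reproduces
them byte for byte.

## File formats

* genotypes: CSV (rows = samples, columns = SNPs, cells `0`/`1`/`NA`) or
  VCF (`GT`; haploid or homozygous diploid; heterozygous calls are set
  missing with a warning),
* genetic map: TSV with `snp_id, chrom, cm`,
* metadata: CSV with `sample_id, role, subpop_id, country, year, state`.
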