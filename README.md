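# clonolink

Paired single-cell transcriptome + TCR/BCR repertoire analysis for
synovium-vs-blood cohort designs, exercised end to end on a bundled
synthetic cohort generator with ground truth.

The package covers:

- **Synthetic cohorts** (`clonolink.simulate`): seeded generator of cell
  metadata, 10x-style contig and AIRR rearrangement tables, a sparse count
  matrix, a germline V/J mini-reference, donor HLA tables and a viral TCR
  reference — with configurable per-tissue subset composition, clone-size
  spectra, per-subset SHM rates and isotype-switch probabilities, receptor
  recovery dropout, cross-tissue clone trafficking, planted HLA-matched viral
  CDR3β sequences and expression shifts in expanded cells. Every cohort
  carries its ground truth for parameter-recovery testing.
- **Ingest & QC** (`clonolink.ingest`): 10x `filtered_contig_annotations.csv`
  and AIRR TSV dialects; top-2 TCR chain retention with single-chain removal;
  BCR chain filters (high-confidence, full-length, CDR3 length, over-chained
  cells); cross-lineage doublet flagging; cell-level QC thresholds.
- **Clonotyping** (`clonolink.clonotyping`): donor-partitioned exact-key TCR
  clones; greedy centroid BCR clustering on IgH CDR3 nucleotide identity
  (default threshold 0.965, configurable); clone-size categories; invariant
  MAIT TCR flagging (TRAV1-2 + TRAJ33/20/12).
- **Clonal analytics** (`clonolink.analytics`): Morisita–Horn overlap
  matrices, per-donor expansion fractions, top-clone composition with
  cross-tissue sharing, trafficking summaries, CDR3 length/charge, paired
  SYN-vs-PBL abundance tests (paired t or Wilcoxon, optional Holm).
- **SHM & isotype** (`clonolink.shm`): nearest-germline assignment with
  V/J substitution counts outside the CDR3, combined V–J SHM rate, class-switch
  classification, a donor-random-intercept linear model of SHM rate
  (statsmodels MixedLM) and a donor-random-intercept logistic model of switch
  state (in-package Gauss–Hermite quadrature ML with Wald CIs).
- **Viral specificity** (`clonolink.specificity`): exact CDR3β + HLA matching
  against a reference table and a simplified motif-enrichment route
  (interior k-mers, one-sided Fisher exact vs background, HLA-restricted
  group filtering) plus matching-vs-non-matching phenotype comparisons.
- **Gene signatures** (`clonolink.signatures`): expression-binned,
  control-subtracted module scores and per-donor expanded-vs-unexpanded
  paired comparisons.
- **Lineage trees** (`clonolink.lineage`): within-clone dendrograms from
  mutation-derived features (Euclidean distances, classical ward.D update),
  serialized to Newick.
- **Pipeline & CLI** (`clonolink.pipeline`, `clonolink.cli`): one-config
  orchestration with per-table config-hash stamping and deterministic reruns.

## CLI

```sh
# generate a synthetic cohort fixture directory
clonolink simulate --preset paper-default --seed 1 --out fixture/

# run everything: ingest -> clonotype -> stats/shm/models/specificity/score/lineage
clonolink run --dir fixture/ --out run/ --seed 1

# or stage by stage
clonolink ingest --contigs fixture/airr_rearrangements.tsv \
    --cells fixture/cells.csv --dialect airr_tsv --out run/
clonolink clonotype --dir run/ --receptor bcr --threshold 0.965 --out clones.tsv
clonolink stats expansion --dir run/ --clones clones.tsv \
    --subset CD4-Tph --tissue SYN --out expansion.tsv
clonolink shm --dir run/ --germline fixture/germline.fasta --out shm.tsv
clonolink models --dir run/ --which switch --shm-records shm.tsv \
    --reference-subset B-naive --out model.tsv
clonolink lineage --dir run/ --clones clones.tsv --shm-records shm.tsv \
    --min-size 3 --out trees/
```

`clonolink run --config cfg.yaml` accepts a YAML file mirroring every
threshold in `clonolink.pipeline.RunConfig`; stage toggles via `--skip`.

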