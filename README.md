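# segmap

Genetic dissection of a quantitative trait with single-segment substitution
lines (SSSLs), from per-line QTL detection through candidate genes:

- **`segmap.sssl_core`** — domain types (genetic map, substituted segments,
  lines), arcsine-square-root transformed two-sample t tests per season,
  additive-effect / contribution estimation on the proportion scale,
  broad-sense heritability from variance components, and block-consistency
  one-way ANOVA.
- **`segmap.substitution_mapping`** — groups overlapping same-sign detections
  into integrated QTLs and localizes each one by closed-interval algebra:
  intersection of member maximal intervals minus the interiors of core
  intervals of overlapping non-significant lines.
- **`segmap.f2_genetics`** — F2 segregation chi-square, the coded
  additive/dominance regression (x ∈ {−1,0,1}, z ∈ {0,1,0}), marker–trait
  Pearson association, and recombinant-progeny fine mapping on physical
  coordinates via the same interval engine.
- **`segmap.bsa_index`** — bulk SNP-index / delta-index computation,
  sliding-window smoothing, Monte-Carlo null confidence bands matched to the
  observed window depth profile, and candidate-interval calling.
- **`segmap.candidate_genes`** — three-stage triage: annotation filter
  (hypothetical-only genes dropped), qualifying-variant filter
  (upstream/exonic InDels and exonic nonsynonymous SNPs at delta-index >
  0.8), and seed-expression filter.
- **`segmap.synthetic_data`** — forward simulators (substitution-line
  libraries with planted effects, Haldane-recombination F2 populations,
  pooled-bulk read depths) for ground-truth testing.
- **`segmap.datasets`** — packaged TSV fixtures: the 24-line detection
  summary with segment definitions and a tuned marker map, the 40-gene
  region table with variant counts and expression categories, and the five
  recombinant populations.

## CLI

```bash
segmap detect    --pheno pheno.csv --parent HJX74 --alpha 0.001 --min-seasons 2 --out det.tsv
segmap integrate --detections det.tsv --segments segs.tsv --map map.tsv --out qtls.tsv
segmap f2        --genotypes f2.tsv --ratio 1:2:1 --out report.json
segmap finemap   --populations recombinants.tsv --alpha 0.01 --out interval.bed
segmap bsa       --variants sites.tsv --pool-size 30 --window 1000000 --step 100000 \
                 --nsim 10000 --seed 1 --out bsa_out/
segmap candidates --genes genes.tsv --assay assay.tsv --delta 0.8 --out report.json
segmap simulate  --n-lines 100 --n-f2 200 --seed 1 --out sim/
```

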