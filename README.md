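# snpsom

Self-organizing-map (SOM) portrayal of disease-associated SNP landscapes
across populations.

Genotype panels (VCF or a plain-text dosage matrix) are coded as
minor-allele scores (0 = homozygous major, 1 = heterozygous, 2 = homozygous
minor), filtered to disease-associated SNPs with MAF > 0.05, and the SNP
frequency profiles are clustered on a 55 × 55 batch SOM (K = 3,025
"meta-SNP" prototypes). Each individual gets a grid-shaped *portrait* of
per-unit mean allele scores; group mean portraits are combined into a
minor-allele summary map, segmented into lettered *spots*, and each spot is
tested for enrichment of level-3 disease-ontology terms with one-sided
Fisher's exact tests. Individuals are related by a minimum spanning tree on
1 − Pearson correlation of their portraits, and the whole pipeline can be
retrained on a sample subset ("zoom-in"). A seeded synthetic-data module
(Balding–Nichols population structure plus planted disease-annotated
minor-allele blocks) provides ground truth for every stage.

## CLI

```sh
# write a synthetic fixture (VCF + metadata + associations + OBO + truth)
snpsom simulate --out fixture/ --seed 1

# full pipeline: filter -> code -> train -> portray -> spots -> enrich -> MST
snpsom run-all \
    --genotypes fixture/genotypes.vcf \
    --sample-table fixture/samples.tsv \
    --associations fixture/associations.tsv \
    --ontology fixture/ontology.obo \
    --out run/ --seed 1 --grid 20x20 --maf 0.05

# zoom-in retraining on selected populations (outputs in run_zoom/)
snpsom zoom --populations POP1,POP2 ... --out run/

# individual stages
snpsom filter / train / portray / spots / enrich / mst --help
```

All settings can also live in a YAML file passed via `--config`; CLI flags
override it. Every run directory contains a `manifest.json` with the
config, seed, per-stage row counts and SHA-256 checksums of all numeric
outputs — reruns with the same config and seed are byte-identical.

## Package layout

| module | contents |
| --- | --- |
| `snpsom.genotype_io` | VCF / matrix input, allele coding, MAF + catalog filters |
| `snpsom.annotation` | association catalogs, OBO parsing, level-3 term mapping |
| `snpsom.som` | batch SOM engine (centralize / train / BMU assignment) |
| `snpsom.portrayal` | individual, mean and difference portraits; ternary PNG rendering |
| `snpsom.spots` | summary map, spot segmentation, Fisher enrichment, background counts |
| `snpsom.similarity` | portrait correlations, MST, zoom-in retraining |
| `snpsom.synthetic` | Balding–Nichols simulator, planted blocks, ontology fixtures |
| `snpsom.pipeline` / `snpsom.cli` | orchestration, manifests, `snpsom` console script |
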