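# hybridpanel

Analysis toolkit for diallel yeast hybrid panels: Gompertz growth-curve
fitting from OD600 plate-reader time series, mid-parent / best-parent
heterosis statistics, genotype-based cross predictions (hybrid
heterozygosity, identity-by-state genetic distance, predicted ploidy), and
the association layer linking ploidy, genetic distance and domestication
status to growth and heterosis. A synthetic diallel-panel generator with a
ground-truth ledger makes every stage testable without external data.

## Modules

| module | what it does |
|---|---|
| `hybridpanel.simulate` | synthetic panels: clade-structured parental genotypes, two mating-competent derivation routes (ploidy-retaining "switch", ploidy-halving "spore" with loss of heterozygosity), all MATa×MATalpha crosses, Gompertz-shaped OD600 series with mid-parent baseline, heterozygosity-linked heterosis and ploidy penalties |
| `hybridpanel.growth` | Zwietering-form Gompertz fits on ln(OD/OD0) (weighted least squares, deterministic multi-start), trapezoid AUC of the fitted curve, replicate means and CVs |
| `hybridpanel.heterosis` | MPH/BPH per hybrid×medium×trait, positivity tallies, parent-representation analysis |
| `hybridpanel.genotypes` | {0, 0.5, 1} genotype matrix from a VCF (quality/biallelic/complete-GT filters), predicted heterozygous sites, IBS0+IBS1 distance, ploidy from a fluorescence standard curve |
| `hybridpanel.associations` | grouped Pearson correlations with Benjamini-Hochberg correction, one-way ANOVA + Tukey HSD with compact letter display, rank-sum tests, DD/DW/WW cross-type labels, ploidy binning, no-intercept regression of log1p(BPH) on genetic distance and ploidy with standardized β |
| `hybridpanel.pipeline` | end-to-end orchestration with input validation, content-hash stage caching and a reproducibility manifest |
| `hybridpanel.design` | constants of the published panel design (18 parents, mating-competent roster sizes, six media) and enumeration helpers |

## CLI

```sh
# generate a synthetic panel (default profile: 18 parents, 6 media, 3 replicates)
hybridpanel simulate --profile small --seed 7 --outdir out/panel

# validate inputs
hybridpanel validate --growth out/panel/growth.tsv \
    --metadata out/panel/metadata.tsv --genotypes out/panel/genotypes.tsv

# individual stages
hybridpanel fit --growth out/panel/growth.tsv --outdir out/run
hybridpanel heterosis --summaries out/run/summaries.tsv \
    --metadata out/panel/metadata.tsv --trait auc --outdir out/run
hybridpanel genotype --matrix out/panel/genotypes.tsv \
    --metadata out/panel/metadata.tsv --outdir out/run

# everything at once (simulate mode, or pass --growth/--metadata/--genotypes)
hybridpanel run-all --profile small --seed 7 --outdir out/full
```

All tables are plain TSV; `manifest.json` records the seed, config hash,
per-stage row counts and warnings. Reruns with identical config and seed
produce byte-identical tables.

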