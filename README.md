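# haplomark

Gene-haplotype characterization and marker design for inbred diversity
panels: haplotype grouping from a gene-region SNP matrix, minimal
discriminating tag-SNP selection, diagnostic-SNP discovery in flanking
sequence, and marker validation by concordance, genotyping QC and trait
association. A synthetic-panel generator with a truth ledger stands in for
the large germplasm panels the workflow was designed around (the motivating
use case is the rice *BADH2* aroma gene and its KASP trait marker).

## Modules

| module | role |
| --- | --- |
| `haplomark.model` | shared types: `VariantSite`, `GenotypeMatrix`, `SampleMeta`, `PhenotypePanel` |
| `haplomark.panel_io` | VCF / matrix-TSV / metadata / phenotype / report readers and writers |
| `haplomark.synth_panel` | synthetic panel, phenotype and genotyping-job simulators + `TruthLedger` |
| `haplomark.hapgroup` | het recoding, missingness filter, Hamming-radius leader clustering, rare/unclassified labeling, subgroups, consensus, crosstab |
| `haplomark.tagselect` | group-consensus MAF, greedy tag selection, exhaustive minimal-set oracle, per-sample tag calling |
| `haplomark.diagsnp` | diagnostic-SNP search over gene + flanking window |
| `haplomark.valmark` | concordance / perfect-LD vs a functional reference marker, assay QC, phenotype association |
| `haplomark.refpanel` | bundled published summary tables (global 2,932-accession panel, 369-line U.S. panel) |

## CLI

All pipeline stages are exposed under a single `haplomark` entry point:

```sh
haplomark simulate --config config.yaml --out-dir sim/ --seed 1
haplomark classify --genotypes sim/genotypes.tsv --meta sim/metadata.tsv \
    --max-mismatch 3 --max-missing-site 100 --min-group-frac 0.01 \
    --out report.tsv --json cls.json
haplomark select-tags --classification cls.json --out tags.json
haplomark call --genotypes sim/genotypes.tsv --tags tags.json --out calls.tsv
haplomark find-diagnostic --genotypes sim/genotypes.tsv --classification cls.json \
    --target-group 6 --gene Chr8:20380000-20385000 --flank 10000 --out candidates.tsv
haplomark validate --calls diag_calls.tsv --reference sim/reference_marker.tsv \
    --mapping T=del,G=nodel --out concordance.json
haplomark qc --jobs jobs.tsv --out qc.json
haplomark associate --classification cls.json --phenotypes sim/phenotypes.tsv \
    --threshold 0.2 --out assoc.json
```

Regions are `CHR:START-END`, 1-based inclusive (converted to 0-based
half-open internally). Genotype matrices are accepted as VCF or as a TSV
with a `sample` column and one `chrom:pos` column per site (`H` =
heterozygous, `.`/`N` = missing).

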