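# Annotation TSV column dictionary

One row per variant, keyed by `variant_id` (`chrom:pos ref>alt`, 1-based).
Unknown columns are ignored; empty cells mean "missing". UTF-8, tab-separated,
`.` decimal point.

| column | type | notes |
|---|---|---|
| `variant_id` | string | unique key, e.g. `3:38613773 G>A` |
| `gene_symbol` | string | HGNC symbol; drives panel membership and inheritance |
| `consequence` | SO term | worst consequence across transcripts (e.g. `missense_variant`, `start_lost`) |
| `protein_change` | string | HGVS-p, optional |
| `gnomad_af` | float in [0,1] | gnomAD allele frequency; decimal or scientific notation |
| `kg_af` | float in [0,1] | 1000 Genomes allele frequency |
| `polyphen` | category or float | `benign` / `possibly_damaging` / `probably_damaging`; numeric scores binned at 0.446 (damaging-spectrum at or above) |
| `sift` | category or float | `tolerated` / `deleterious`; numeric scores binned at 0.05 (deleterious below) |
| `cadd_phred` | float >= 0 | CADD phred score |
| `fathmm` | category | `tolerated` / `damaging` |
| `clinvar` | category | `Pathogenic`, `Likely pathogenic`, `P/LP`, `VUS`, `Conflicting`, `Likely benign`, `Benign`, or empty (`not_found`) — case-insensitive |
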