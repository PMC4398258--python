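# cageatlas

A toolkit for promoter-level analysis of CAGE (Cap Analysis of Gene
Expression) 5'-tag data, plus a synthetic CTSS generator with planted,
recoverable structure for validating every stage of the pipeline.

What it does:

- **TSS atlas** (`cageatlas.atlas`): single-linkage clustering of stranded
  per-base tag counts into TSS regions, tags-per-million normalisation,
  expression filtering (max TPM >= 5 by default), and annotation against gene
  models (promoter within 500 bp of a same-strand transcript 5' end,
  intragenic inside a same-strand gene body, else intergenic), plus overlap
  of intergenic TSSs with noncoding interval sets.
- **Promoter usage** (`cageatlas.usage`): TSS-per-gene distributions,
  per-sample vs atlas-wide usage contrast via a two-sided Fisher exact test,
  and per-cell-type up/down signature gene calls.
- **Coexpression** (`cageatlas.coexpression`): Pearson correlation graphs on
  log2(TPM+1) with a hard cutoff, a full Markov cluster algorithm
  implementation (inflation 2.2 by default), cluster size/gene filters
  (>= 20 members, >= 5 genes), cluster mean profiles, and a stage-ordered
  trajectory variant for maturation series.
- **Enrichment** (`cageatlas.enrichment`): a log2-odds PWM scanner over both
  strands (JASPAR-style matrices), upper-tail hypergeometric enrichment with
  Benjamini-Hochberg FDR, and interval-overlap enrichment against peak sets.
- **Enhancers** (`cageatlas.enhancers`): balanced bidirectional transcription
  at non-genic loci (divergent cluster pairs within 400 bp, |D| <= 0.8 where
  D = (F-R)/(F+R) on pooled counts), cell-type restriction calls, and
  enhancer-gene linking by expression correlation within 500 kb.
- **Simulator** (`cageatlas.simulate`): negative-binomial tag counts over a
  toy genome with cell-type-specific promoter modules, alternate promoters,
  planted motifs, balanced bidirectional enhancer loci, background and noise
  TSSs, and library-size variation. Everything planted is reported in a
  truth-table JSON; identical configs produce byte-identical outputs.

## Command line

The `cageatlas` entry point chains the whole pipeline:

```sh
cageatlas simulate --out sim/ --seed 42                 # synthetic data + truth.json
cageatlas tss --ctss-dir sim/ctss --gtf sim/genes.gtf \
    --max-gap 20 --min-tpm 5 --out atlas.tsv            # TSS atlas (TSV + BED)
cageatlas cluster --matrix atlas.tsv --level tss \
    --cutoff 0.9 --inflation 2.2 --out clusters/        # MCL coexpression clusters
cageatlas enrich --clusters clusters/clusters.tsv --atlas atlas.tsv \
    --fasta sim/genome.fa --pwm sim/pwms.jaspar --out enrich.tsv
cageatlas enhancers --atlas atlas.tsv --gtf sim/genes.gtf \
    --samples sim/samples.tsv --out enhancers/
cageatlas usage --atlas atlas.tsv --samples sim/samples.tsv --out usage/
```

`cageatlas simulate` accepts a YAML config (`--config cfg.yaml`) overriding
any `SimConfig` field, and `--trajectory` additionally emits a stage-ordered
gene expression matrix for `cageatlas cluster --level trajectory`.

## File formats

All in-memory coordinates are 0-based half-open; GTF (1-based closed) is
converted at the boundary. CTSS tracks are BED6 with one row per
(position, strand) and the raw integer tag count in the score column.
Expression matrices are TSV with a `feature_id` column; the atlas TSV embeds
per-sample `count:`/`tpm:` columns and the library sizes in a header
comment, and round-trips losslessly.
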