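# vulnprior

Prioritize druggable, cancer-type-specific therapeutic targets from
genome-wide CRISPR gene-dependency screens, validate them against inhibitor
response data, and discover genetic biomarkers of dependency.

The pipeline consumes DepMap-style matrices (Chronos gene-effect scores and
gene-dependency probabilities), cell-line annotations, mutation tables,
expression/copy-number matrices, GDSC-style drug-response tables, and
TCGA-style tumour tables. A synthetic-panel generator with planted ground
truth stands in for all of these downloads, so the whole pipeline is
testable offline.

## What it does

1. **Filtration waterfall** (`vulnprior.prioritization`) — call a gene
   essential in a line when its dependency probability is ≥ 0.5; keep genes
   essential in ≥ 1 line; intersect with a druggable gene list; remove
   common-essential and core-fitness genes (no therapeutic window); remove
   genes dependent in < 9% of the panel; rank survivors by dependency
   frequency, then median gene-effect score over the dependent lines. Every
   stage is recorded in an audit whose conservation law (`n_in = n_out +
   |removed|`) is enforced.
2. **Drug-response validation** (`vulnprior.drug_validation`) — stratify
   lines into high / intermediate / low dependency by effect-score
   quartiles and test whether high-dependency lines respond more strongly
   (Welch ANOVA + Dunnett contrasts against the low stratum; Welch t or
   Mann–Whitney with two strata).
3. **Biomarker discovery** (`vulnprior.biomarker`) — mutation–dependency
   association screen gated on p < 0.05 **and** |Cohen's d| ≥ 1;
   dependency–expression/copy-number Pearson correlation; GISTIC
   classification, co-amplification frequencies, amplification-stratified
   Mann–Whitney comparisons; Kaplan–Meier + log-rank survival.
4. **Statistical kernels** (`vulnprior.stat_core`) — Welch/Student t,
   exact + normal-approximation Mann–Whitney, Welch ANOVA, seeded
   Monte-Carlo Dunnett adjustment, Holm–Šidák, Cohen's d, Pearson r with
   t-distribution p. All two-sided, all oracle-tested.
5. **Synthetic panels** (`vulnprior.synthetic_panel`) — seed-deterministic
   study bundles with planted targets, associations, amplicons, drug
   responses and survival structure; byte-identical files per seed.

## CLI

```bash
# generate a synthetic bundle with planted truth
vulnprior simulate --seed 17 --out bundle/

# run the filtration waterfall
vulnprior prioritize --effect bundle/effect.csv --probability bundle/probability.csv \
    --annot bundle/annotations.csv --lines-rule "subtype=HNSCC,hpv_status=negative|subtype=ESCC" \
    --druggable bundle/druggable.txt --common-essential bundle/common_essential.txt \
    --core-fitness bundle/core_fitness.txt --out run/

# drug validation / association screen / copy number / survival
vulnprior validate-drugs --effect bundle/effect.csv --drug-response bundle/drug_response.csv \
    --targets run/targets.txt --out run/
vulnprior associate --effect bundle/effect.csv --mutations bundle/mutations.csv \
    --targets run/targets.txt --out run/
vulnprior copy-number --calls bundle/tumour_gistic.csv --anchor TGT0000 \
    --partners PIK3CA,SOX2,ETV5 --out run/
vulnprior survival --tumours bundle/tumours.csv --calls bundle/tumour_gistic.csv \
    --anchor TGT0000 --out run/

# everything at once, from a config file, with a stitched Markdown report
vulnprior run-all --config run.ini --out run/
vulnprior compare-releases --list-a old.txt --list-b new.txt
```

`run-all` reads a flat INI config (`[inputs]`, `[options]`, `[thresholds]`
sections); every flag overrides its config key and the effective config is
echoed into the report.

## Layout

```
src/vulnprior/
  panel_io.py         # formats, validation, canonical data model
  prioritization.py   # the filtration waterfall + audit
  drug_validation.py  # dependency-quartile drug-response comparison
  biomarker.py        # mutation/expression/copy-number/survival biomarkers
  stat_core.py        # shared statistical kernels
  synthetic_panel.py  # planted-truth study generator
  cli.py              # command-line front end + run report
tests/                # unit, property, and acceptance suites
scripts/acceptance.py # acceptance report generator
```
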