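# sarqc

Curation and quality flagging of literature-extracted bioactivity data.

Structure–activity records harvested from the medicinal-chemistry
literature arrive messy: the same endpoint published under dozens of type
spellings ('Half life', 'T1/2', 't(1/2)') and unit dialects ('uM',
'umol/L', 'micromolar'), logarithmic types mixed with linear ones, values
missing, re-cited from earlier papers (often rounded), or mis-copied with
the wrong units — an exact 10³ or 10⁶ fold error. `sarqc` is for anyone
building SAR datasets, QSAR models or chemogenomics analyses from such
records: it standardizes each measurement, flags integrity problems
without deleting anything, and computes pChEMBL for clean dose–response
data.

The pipeline runs seven steps in order:

| # | step | annotation |
|---|------|------------|
| 1 | flag missing activities | `Potential missing data` |
| 2 | flag non-standard units for the type | `Non standard unit for type` |
| 3 | convert log types (pKi → Ki in nM, relation flipped) | — |
| 4 | flag out-of-range values (0.01 nM – 100 µM for dose–response; upper bound ×100 for fragments, MW < 350) | `Outside typical range` |
| 5 | flag cross-publication duplicate citations (equal values, or equal after 1–3 sig-fig rounding) | `potential_duplicate` |
| 6 | flag unit transcription errors (matching mantissa, 3 or 6 decades apart; later paper flagged) | `Potential transcription error` |
| 7 | compute pChEMBL = −log₁₀(activity in M) = 9 − log₁₀(value/nM) | `pchembl_value` |

Standard values are rounded arithmetically (half-up): 3 significant
figures below 10, two decimals otherwise. Published fields are preserved
verbatim, one validity comment per record, and the pipeline is
deterministic and idempotent. All rules — type synonyms, unit dialects,
allowed units, typical ranges, unlogging, assay keywords, the cell-line
dictionary — live in a versioned YAML configuration with an extensible
default shipped in the package.

A seeded synthetic-corpus generator produces literature-style messy data
with ground-truth labels for every injected defect (citations, decade
slips, missing values), so the precision and recall of each flag can be
measured without any external database. Rule-based assay annotation
(B/F/A/T/P assay types, biochemical/cell/tissue/organism formats,
ambiguous cell-line tokens) and target-taxonomy validation (SINGLE
PROTEIN, PROTEIN FAMILY, PROTEIN COMPLEX, PROTEIN COMPLEX GROUP) round
out the toolkit.

## Worked example

```python
from sarqc import (default_config, GeneratorParams, generate_corpus,
                   run_pipeline, evaluate_flags)

cfg = default_config()
params = GeneratorParams(n_compounds=60, n_targets=4, n_documents=25, seed=11)
records, compounds, assays, truth = generate_corpus(params, cfg)
curated, report = run_pipeline(records, compounds, assays, cfg)
for row in report.rows:
    print(f"{row.order}  {row.step:<45} {row.count:>5}  {row.percentage:>6.2f}%")
```

prints, for this 858-record corpus:

```
1  Flag missing activities                           7    0.82%
2  Flag non-standard units for activity type         0    0.00%
3  Convert log activity values                     185   21.56%
4  Flag out of range values                         48    5.59%
5  Flag potential duplicate values                  30    3.50%
6  Flag potential transcription errors              16    1.86%
7  Calculate standard negative log values          787   91.72%
```

i.e. 7 records had no value or comment, 185 arrived as pKi/pIC50-style
logs and were unlogged, 48 standardized values fell outside the typical
range, 30 were re-citations of an earlier paper's measurement, 16 were
decade slips, and 787 clean dose–response records received a pChEMBL.
Scoring the flags against the generator's ground truth:

```python
for name, m in evaluate_flags(curated, truth).items():
    print(name, "precision", m.precision, "recall", m.recall)
```

```
missing precision 1.0 recall 1.0
duplicate precision 1.0 recall 1.0
transcription precision 0.9375 recall 1.0
out_of_range precision 1.0 recall 1.0
```

Every injected defect is recovered; the one transcription false positive
is an honest coincidence (an independent value landing a rounded decade
from another). A single record shows the standardization itself:

```
R000000  EC50 = 2.36947e-06 M  ->  EC50 = 2369.47 nM,  pChEMBL 5.63
```

The same workflow is available from the shell:

```bash
curate simulate --seed 11 --out-dir corpus/
curate run --records corpus/records.csv --compounds corpus/compounds.csv \
           --assays corpus/assays.csv --out curated.csv --report report.json
curate evaluate --records curated.csv --truth corpus/truth.csv
curate validate-config --config my_rules.yaml
```

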