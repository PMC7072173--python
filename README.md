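# snocna

Co-alteration analysis of intronic snoRNAs and their host genes across
tumor cohorts.

About half of human small nucleolar RNAs (snoRNAs) sit inside introns of
host genes and are co-transcribed with them, so one would expect somatic
copy-number alteration (CNA) to hit a snoRNA and its host together. In
tumor genomes this is often, but not always, true — and the exceptions
(snoRNA altered without its host, or vice-versa) are interesting in their
own right. `snocna` is for computational cancer biologists who have
gene × sample matrices of discrete copy-number calls and expression values
(e.g. cBioPortal `data_CNA` / RSEM extracts) plus a snoRNA→host pairing
table, and want reproducible couple-level co-alteration statistics.

## What it computes

For each snoRNA/host *couple* c and sample s, with GISTIC codes
g ∈ {−2, −1, 0, +1, +2}, an event is a deep call (|g| = 2, amplification or
deep deletion). Each (c, s) cell is classified as `none`, `snorna_only`,
`host_only` or `co_occurring`, and per cohort the package reports:

* cumulative CNA frequency = altered cells / (couples × samples), missing
  cells excluded from both sides;
* per-sample event rates and amplification/deletion breakdowns by context;
* the never / all / some partition of couples by the cohorts in which they
  are ever altered;
* top-k most recurrently altered couples (deterministic tie-breaks);
* diploid-referenced expression Z-scores, z = (x − μ_ref)/σ_ref with the
  reference restricted to samples diploid for the gene; calls `up` (z > 2)
  and `down` (z < −2), per-sample rates, top-k up-regulated couples, and
  CNA↔expression concordance;
* per-couple Fisher exact tests (written from first principles, two-sided
  probability method) of "snoRNA altered" × "host altered", with
  Benjamini–Hochberg adjustment.

A seeded generator produces multi-cohort synthetic inputs with known joint
alteration structure and dosage-coupled expression, so the entire pipeline
is testable without downloads. See `docs/methods.md` for the model details
and assumptions.

## Worked example

Command line — simulate a strongly co-occurring cohort, analyze it, and
summarize:

```sh
snocna simulate --preset kirc_like --seed 1 --out sim
snocna run --config sim/inputs.yaml --out results
snocna report --results results
```

Python API, same data:

```python
from snocna import align_couples, generate, summarize_cohort, top_k_couples
from snocna.simulate import get_preset

result = generate(get_preset("kirc_like", seed=1))
cohort = result.cohorts[0]
summary = summarize_cohort(cohort, align_couples(result.couples, cohort))
print(summary.cell_counts)
print(round(summary.cumulative_frequency, 5))
print(top_k_couples(summary, k=3)[["rank", "label", "altered_fraction"]])
```

prints

```
{'none': 103810, 'snorna_only': 80, 'host_only': 79, 'co_occurring': 461}
0.00594
   rank            label  altered_fraction
0     1  SNORD233S/HG233          0.019774
1     2  SNORA260S/HG260          0.016949
2     3  SNORD149S/HG149          0.016949
```

Of 295 couples × 354 samples, 620 cells carry a deep CNA (cumulative
frequency 0.0059, a low-burden cohort), and co-occurring cells (461)
outnumber single-member cells (159) roughly 3:1 — the signature of the
`kirc_like` preset, whose couples are jointly altered 75% of the time. The
top couples are altered in ~2% of samples. `snocna run` writes one TSV per
result (cell counts, frequencies, rankings, Z-scores, association tests)
plus a manifest with the resolved configuration and input checksums;
`snocna report` condenses them to the plain-text summary above.

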