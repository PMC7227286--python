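# burdenalign

Tools for asking whether health research effort lines up with health need.
`burdenalign` classifies diseases by where their burden falls — high-income
countries (HICs) versus low- and middle-income countries (LMICs) — attributes
scientific publications to country income groups by fractional counting, and
computes alignment and visibility indicators for any aggregate of
publications: publication and DALY shares, relative research effort,
Q1-journal shares, and field-normalised citation scores. It is aimed at
research-policy analysts and scientometricians who want a reproducible,
testable pipeline for burden-vs-output analyses, and it ships a synthetic
world generator so every stage can be exercised without access to
bibliographic databases.

## The model

**Disease typology.** For each disease, the relative burden per capita is

```
r = (DALY_LMIC / pop_LMIC) / (DALY_HIC / pop_HIC)
```

where the LMIC pool aggregates DALYs and populations over upper-middle-,
lower-middle- and low-income countries (a single pooled rate). The ratio bins
diseases into five types (lower bounds inclusive):

| type | ratio | reading |
|------|-------|---------|
| 1a | r < 0.75 | more burden in HICs |
| 1b | 0.75 ≤ r < 1.25 | equal burden |
| 1c | 1.25 ≤ r < 3.00 | a bit more burden in LMICs |
| 2  | 3.00 ≤ r < 35.0 | more burden in LMICs |
| 3  | r ≥ 35.0 | quasi-exclusive of LMICs |

**Counting.** Publications are attributed to countries by fractional
counting: each author-affiliation instance carries 1/n of the publication, so
every paper contributes one unit of credit. A paper listing two or more
distinct countries is an international collaboration. Papers matching several
diseases split their credit equally (configurable).

**Indicators.** For an aggregate *S* (a disease type, an income group, a
pharma subset, …):

- *relative research effort* = (share of publications of *S*) / (share of
  DALYs of *S*); 1 means attention proportional to burden;
- *Q1 share* = weighted fraction of *S* published in journals in the top
  impact-factor quartile of their subject category and year;
- *MNCS* = mean of citations / world mean citations of the same field and
  year (world average = 1);
- *PPtop10%* = share of *S* among the world's 10% most cited publications of
  their field and year, with ties at the threshold counted fractionally so
  the world value is exactly 10%.

## Worked example

Run the full pipeline on a default synthetic world (134 diseases, four
income groups, 200 journals, 10,000 publications):

```python
import burdenalign as ba

cfg = ba.RunConfig(synthetic=True, seed=7)
cfg.world_config.seed = 7
cfg.corpus_config.seed = 8
cfg.corpus_config.total_publications = 10000
bundle = ba.run_pipeline(cfg)
print(bundle.table_relative_effort.round(3).to_string(index=False))
```

```
disease_type  pub_share  daly_share  relative_effort
          1a      0.372       0.269            1.384
          1b      0.262       0.138            1.902
          1c      0.184       0.194            0.952
           2      0.114       0.204            0.562
           3      0.067       0.196            0.340
```

Type-1a diseases receive 37% of publications against 27% of DALYs (relative
effort 1.38 — over-researched relative to burden), while type-3 diseases get
0.34 publications per unit of burden — the HIC-skew pattern the default
synthetic configuration encodes. The citation table from the same run shows
the configured visibility gradient:

```
print(bundle.table_q1_and_citations.round(3).to_string(index=False))

disease_type  n_fractional  q1_share  mncs  pp_top10
          1a        3543.0     0.249 1.113     0.130
          1b        2495.0     0.254 1.002     0.095
          1c        1754.0     0.258 0.949     0.090
           2        1088.0     0.263 0.858     0.068
           3         634.0     0.273 0.743     0.036
```

Type-1a papers are cited 11% above the world field-year average, type-3
papers 26% below, while Q1-journal access is nearly flat across types.

The same analysis runs from files (disease concordance CSV, DALY and
population tables, income table, corpus JSONL, journal table) via the CLI:

```
burdenalign simulate --seed 7 --out inputs/   # or bring your own files
burdenalign run --synthetic --seed 7 --out tables/
burdenalign classify --burden burden.csv --population population.csv
```

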