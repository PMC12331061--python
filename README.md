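# faersig

Pharmacovigilance signal detection and time-to-onset modelling for
FAERS-style spontaneous adverse-event report data.

## The problem

Post-marketing safety surveillance asks whether a drug and an adverse
event are reported together more often than chance would predict in a
spontaneous-report database such as the FDA Adverse Event Reporting
System (FAERS). `faersig` implements the standard screening workflow for
a single index drug against the full reporting background:

1. **Ingestion and deduplication** of the quarterly `'$'`-delimited ASCII
   tables (DEMO, DRUG, REAC, THER, OUTC). A case (`CASEID`) may carry
   several report versions (`PRIMARYID`); within a case the version with
   the largest `FDA_DT`, then the largest `PRIMARYID`, survives.
2. **Contingency construction** at the MedDRA preferred-term (PT) and
   system-organ-class (SOC) level. The counting unit is the unique
   (report, PT) pair, so for each event label
   `a` = index-drug reports with the event, `b` = remaining index-drug
   pairs, `c`, `d` likewise for all other drugs, and
   `E = (a+b)(a+c)/N` is the independence expectation.
3. **Four disproportionality statistics** per cell:
   - reporting odds ratio `ROR = ad/bc` with the Woolf 95% CI;
   - proportional reporting ratio `PRR = [a/(a+b)]/[c/(c+d)]` with its
     log-normal CI and the Yates-corrected chi-square;
   - BCPNN information component `IC = log2` of the shrunken
     observed-to-expected ratio — both the original Bayesian formulation
     (exact posterior moments, `IC025 = E[IC] - 2*SD`) and the Norén
     expected-count form with its closed-form credibility bound;
   - MGPS: a two-component gamma mixture prior over the relative
     reporting rate, fitted by marginal maximum likelihood across every
     drug-event cell, giving the empirical-Bayes geometric mean `EBGM`
     and its posterior 5th percentile `EBGM05`.

   A PT is a **signal** only when all criteria hold simultaneously:
   `a >= 3`, ROR CI lower bound > 1, `PRR >= 2` with chi-square > 4,
   `IC025 > 0`, `EBGM05 > 2`.
4. **Time-to-onset modelling.** Onset = event date minus therapy start
   date in whole days (partial dates and negative intervals excluded and
   tallied; day-0 onsets imputed to half a day). A two-parameter Weibull
   is fitted by maximum likelihood; the shape CI classifies the hazard as
   *early failure* (upper CI < 1), *random failure* (CI spans 1), or
   *wear-out failure* (lower CI > 1). Onsets are compared between sexes
   with a Wilcoxon rank-sum test (exact enumeration for small groups).
5. **Descriptives**: a Table-1-style clinical-characteristics summary
   with explicit "Not specified" rows and half-up 2-decimal percentages.

Because MedDRA is licensed, the PT→SOC mapping is always user-supplied
(a two-column CSV); the bundled synthetic generator uses its own flat
vocabulary. The synthetic module (`faersig.synthetic`) emits schema-valid
FAERS-dialect tables with planted signals of known strength, duplicate
report versions, realistic missingness and Weibull onset times, plus a
ground-truth ledger — every downstream stage is testable without any
download.

## Worked example

```python
import faersig as fs

cfg = fs.SyntheticConfig(n_reports=20000, seed=7)   # 3 planted signals, rate x10
bundle = fs.generate_dataset(cfg)

demo = fs.deduplicate(bundle.tables["DEMO"])
survivors = set(demo["primaryid"])
index_ids = fs.select_primary_suspect(bundle.tables["DRUG"], ["osilodrostat"]) & survivors

reac = bundle.tables["REAC"]
events = reac[reac["primaryid"].isin(survivors)][["primaryid", "pt"]]
cells = fs.build_pt_tables(events, index_ids)

drug = bundle.tables["DRUG"]
ps = drug[drug["role_cod"] == "PS"].drop_duplicates("primaryid")
all_cells = fs.build_drug_event_cells(events, ps.set_index("primaryid")["drugname"])

res = fs.DisproportionalityModel(cells, all_cells).fit()
print(res.rank(by="ror", n=5)[["label", "a", "ror", "ror_lo", "prr",
                               "chi2", "ic025_bate", "ebgm05"]]
      .to_string(index=False, float_format=lambda x: f"{x:.2f}"))

onsets, tallies = fs.link_onset(demo, bundle.tables["THER"], index_ids,
                                bundle.tables["DRUG"], ["osilodrostat"])
tres = fs.WeibullOnsetModel.from_dataframe(onsets).fit()
print(tres.summary())
```

prints

```
 label   a  ror  ror_lo  prr    chi2  ic025_bate  ebgm05
pt_030 816 8.63    7.80 7.92 2408.06        1.97    3.97
pt_040 641 8.52    7.60 7.97 1890.61        1.96    3.93
pt_048 572 8.44    7.48 7.96 1681.45        1.95    3.90

Weibull time-to-onset fit (n=918)
  scale alpha: 184.19 days (95% CI 167.43 - 202.63)
  shape beta : 0.71 (95% CI 0.68 - 0.75)
  empirical median (IQR): 107.50 (33.00, 288.00) days
  failure type: early failure
  log-likelihood: -5804.296
```

The screen recovers exactly the three planted terms — their generative
reporting-rate ratio is 10, attenuated to ~8.6 on the pair-counted odds
scale because three terms are planted at once — and the onset fit
recovers the generative Weibull (scale 187.21 d, shape 0.73; a shape
whose CI sits below 1 is an early-failure hazard). `EBGM05` is smaller
than `ROR` by design: the empirical-Bayes fit shrinks toward the
whole-corpus expectation.

The same pipeline runs from the shell:

```bash
faersig report --out-dir out --seed 7      # simulate -> screen -> TTO -> Table 1
faersig simulate corpus --n-reports 5000 --seed 1
faersig signals corpus --out signals.csv --variant bate
```

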