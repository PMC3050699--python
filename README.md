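# gmoequiv

Difference and equivalence testing for the comparative safety assessment
of genetically modified (GM) crop varieties.

## The problem

In the comparative approach to GM risk assessment a GM variety is grown in
multi-site field trials next to its conventional near-isogenic counterpart
and a set of commercial **reference varieties** with a history of safe use.
Two complementary questions are asked for every measured characteristic
(composition, agronomy, phenotype):

* **Difference** — is the GMO different from its counterpart?  A classical
  two-sided test; a significant result flags a potential unintended effect.
* **Equivalence** — does the GMO stay within the range of natural variation
  shown by the reference varieties?  Absence of a significant difference is
  *not* evidence of equivalence, so a proper equivalence (TOST-style) test
  with explicit limits is needed — and because no agreed equivalence factor
  exists for crop composition, the limits themselves are **estimated from
  the reference varieties** in the same trial.

`gmoequiv` implements this workflow end to end: preprocessing of plot-level
data, REML estimation of the underlying linear mixed models, data-driven
equivalence limits, the four tests, the seven-outcome classification, the
three-scale graphical presentation, and a simulation engine that verifies
the size and power of the whole procedure.

## The model

Measurements are analysed on the natural-log scale.  For plot *ijkl*
(site *i*, block *j*, genotype group *k*, genotype *l*):

```
y_ijkl = Mean + Site_i + Block_ij + GenotypeGroup_k + [genotype term] + e_ijkl
```

with independent normal random effects: `Site ~ N(0, V_s)`,
`Block ~ N(0, V_b)`, genotype `~ N(0, V_g)`, residual `~ N(0, V_e)`.
`GenotypeGroup` (counterpart / GMO / reference) is fixed and carries the
two contrasts of interest, `m_G − m_C` (GC) and `m_G − m_R` (GR).  Two
variants of the random genotype term are used:

* **model 1** — only reference genotypes get random effects: contrasts are
  judged against plot error (difference test, E2/E3 intervals);
* **model 2** — every genotype gets one: the spread between reference
  varieties enters the GR standard error (equivalence limits, test E1).

Both variants share identical REML variance components and group means;
their standard errors of difference obey `sed_GC;2² = sed_GC;1² + 2V_g`
and `sed_GR;2² = sed_GR;1² + V_g` exactly.  Degrees of freedom use the
Kenward–Roger small-sample method (Satterthwaite available via config).

The assessment of one characteristic is then:

1. **D** — significant iff the two-sided 90% CI `m_G − m_C ± lsd(GC;1;95)`
   excludes 0;
2. **limits** — `EL = m_R ± lsd(GR;2;97.5)`, i.e. 95% confidence limits
   around the reference mean under model 2;
3. **E1** ("shared risk") — equivalence more likely than not iff `m_G`
   lies inside `[EL_L, EL_U]`;
4. **E2 / E3** — equivalence (non-equivalence) proven iff
   `m_G ± lsd(GR;1;95)` lies entirely inside (outside) the limits.

The joint verdict is one of seven outcome types grouped in four
categories: (i) equivalence proven, (ii) equivalence more likely than
not, (iii) non-equivalence more likely than not, (iv) non-equivalence
proven.  If `V_g` is estimated at the zero boundary, limits degenerate
and no equivalence conclusion is drawn.

## Worked example

The package ships the per-analyte summaries of a real four-site maize
grain study (53 analytes; one GM variety, one counterpart, 13 reference
varieties).  Re-running the whole assessment:

```bash
python examples/reassess_published_maize_study.py
```

prints

```
analytes assessed:                 53
significant GMO-counterpart diffs: 23
equivalence proven (E2):           44
equivalence more likely (cat ii):  Lysine, Phosphorus, Potassium, Vitamin B6, Vitamin E
outside limits (E1):               16:0 Palmitic, Niacin
no conclusion (zero genotype var): Ash, Phytic acid

Niacin (outcome type 6, category iii):
  geometric means: counterpart 18.2, GMO 15.9, reference 20.9
  equivalence limits, natural scale: [16.1, 27.1]
  GMO vs reference interval (E1):    [0.59, 0.99]  <- excludes 1, so non-equivalence is more likely than not
  GMO/counterpart 90% CI (test D):   [0.841, 0.904]  <- excludes 1, so the difference is significant
```

Read: 23 of 53 analytes differ significantly between GMO and counterpart,
but only two (palmitic acid, niacin) fall outside the natural variation of
the reference varieties — niacin is 24% below the reference mean and also
13% below the counterpart, so it needs further evaluation; 44 analytes are
formally proven equivalent.

Other entry points:

* `examples/assess_field_trial.py` — plot-level CSV in, verdicts out
  (including the genotype-by-site interaction Wald test);
* `examples/power_of_equivalence_tests.py` — operating characteristics of
  the four tests under the default simulation scenario;
* `gmoequiv assess <table.csv>` / `gmoequiv simulate <scenario.yaml>` —
  the same workflows from the shell, writing tidy CSVs and plots.

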