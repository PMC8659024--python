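# tagmrm

Design and evaluation toolkit for targeted LC-MS/MS (MRM) screening of a
urinary preeclampsia biomarker peptide detected via **fixed-charge
derivatization**.

Lysine-terminated tryptic peptides ionize poorly and are usually passed over
as MS biomarkers. Condensing a 2,4,6-triphenylpyrylium (TPP) salt with the
ε-amine of a C-terminal lysine forms a 2,4,6-triphenylpyridinium tag carrying
a permanent +1 charge, which boosts ionization efficiency by roughly three
orders of magnitude — enough to push the detection limit of the podocin
tryptic peptide MIAAEAEK from the femtomole to the attomole range. `tagmrm`
implements the computational side of that workflow:

* **`tagmrm.digestion`** — in-silico tryptic digestion (cleave after K/R, not
  before P), with coordinates, missed cleavages and candidate flags
  (C-terminal lysine = taggable; methionine = oxidation-prone warning).
* **`tagmrm.chem`** — elemental-composition mass calculus with fixed-charge
  bookkeeping. For a species of atomic monoisotopic mass *M* carrying *f*
  fixed charges at total charge *z*:

  ```
  m/z = (M + (z − f) · 1.007276) / z
  ```

  The TPP tag contributes a net composition delta of +C23H15 and *f* = 1
  (pyrylium adds C23H17O⁺, condensation expels H₂O taking two amine
  hydrogens); its reporter ion is protonated triphenylpyridine, C23H18N⁺.
* **`tagmrm.transitions`** — MRM transition lists for native, Met-oxidized
  (+15.99491), carbamidomethylated and TPP-tagged variants, CSV export, and
  annotation of instrument transition lists against theory within ±0.1 m/z.
* **`tagmrm.mrm_sim`** — synthetic MRM chromatograms (Gaussian peak, linear
  amount→area response, additive noise), robust S/N estimation
  (median/MAD baseline, 3:1 detection rule), detection-limit series and
  linear calibration fits.
* **`tagmrm.diagnostics`** — screening performance from 2×2 tables:
  sensitivity/specificity/prevalence/accuracy with exact Clopper–Pearson
  intervals, likelihood ratios with Simel log-method intervals, predictive
  values with Mercaldo logit-method intervals, plus percent-change arithmetic
  for paired ELISA concentrations with `undetectable` handling.
* **`tagmrm.cohort`** — seeded synthetic screening cohorts (fixed prevalence,
  per-week call sensitivity/specificity, log-normal assay levels) so the
  whole evaluation pipeline runs end-to-end without patient data.

## Worked example

Build the transition list for the TPP-tagged peptide at precursor charge 2:

```python
from tagmrm import build_transitions

tl = build_transitions("MIAAEAEK", {2}, series=("y",), variants=("tpp",), top_n=3)
print(tl.to_dataframe())
```

```
 peptide variant  precursor_mz  precursor_charge  product_mz ion_label
MIAAEAEK     tpp      576.7756                 2   1021.5035        y7
MIAAEAEK     tpp      576.7756                 2    908.4194        y6
MIAAEAEK     tpp      576.7756                 2    837.3823        y5
MIAAEAEK     tpp      576.7756                 2    308.1439  reporter
```

The precursor is the [M + H]²⁺ ion of the tagged peptide (one fixed charge +
one proton), printed 576.78 at 2 dp; the reporter 308.14 is the protonated
triphenylpyridine fragment that confirms the tag. Evaluating a screening
week from a cohort table:

```python
from tagmrm import ConfusionTable, render_report
from tagmrm.diagnostics import table_report

print(render_report(table_report(ConfusionTable(TP=6, FN=1, TN=19, FP=2))))
```

```
                Statistic  Value               95% CI
              Sensitivity 85.71% From 42.13 to 99.64%
              Specificity 90.48% From 69.62 to 98.83%
Positive likelihood ratio   9.00   From 2.33 to 34.80
Negative likelihood ratio   0.16    From 0.03 to 0.97
       Disease prevalence 25.00% From 10.69 to 44.87%
Positive predictive value 75.00% From 43.69 to 92.06%
Negative predictive value 95.00% From 75.48 to 99.15%
                 Accuracy 89.29% From 71.77 to 97.73%
```

A sensitivity of 85.71% with an exact CI reaching down to 42% reflects the
tiny outcome group (6 of 7 cases called); statistics a zero cell leaves
undefined render as blank, never as infinity.

A CLI mirrors the library: `tagmrm digest`, `tagmrm transitions`,
`tagmrm annotate`, `tagmrm make-cohort`, `tagmrm evaluate`,
`tagmrm elisa-change` (see `tagmrm --help`).

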