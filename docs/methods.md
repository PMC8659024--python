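# Methods

## Mass calculus

Peptide masses are monoisotopic, assembled by element counting: residue
compositions and element masses come from the standard tables shipped with
pyteomics, summed with a water terminus and any modification deltas. The
proton mass is taken as 1.007276 Da. Electron mass is neglected for cations;
the resulting error (≈ 5.5 × 10⁻⁴ Da) is two orders of magnitude below the
±0.1 m/z matching tolerance used throughout and does not move any value at
the 2-dp display precision.

Fixed-charge bookkeeping is explicit: a species carrying *f* fixed charges at
total charge *z* acquires only *z − f* protons, so a singly charged y-ion
containing the tag is the bare cation with no proton added, and the tagged
precursor at *z* = *f* has m/z = *M*/*z* exactly.

The TPP tag is modeled as a composition delta of +C23H15 with one fixed
charge, restricted to lysine (the ε-amine is the reactive site; α-amine
tagging is not modeled, and at most one modification may occupy a site). Its
reporter ion is stored as the intact cation composition C23H18N⁺ (protonated
2,4,6-triphenylpyridine), so reporter m/z is simply composition mass over
charge. Oxidation (+O on Met) and carbamidomethylation (+C2H3NO on Cys)
carry no fixed charge. Additional tags can be declared in a YAML config
(delta, fixed charge, site residues, reporter).

Display rounding is half-away-from-zero at 2 dp, the convention of printed
transition lists; an input is first rounded at the 8th decimal so that binary
float representation cannot flip a half-case.

Instrument-optimized transition lists deviate from theory by up to ~0.06 m/z
on a unit-resolution triple quadrupole, so annotation matches at a default
tolerance of ±0.1 on both precursor and product, breaking ties by smallest
combined deviation and then lower fragment index. Exact 2-dp agreement with
theory is expected only for values that are theoretically consistent (the
tagged precursor/y3 and the oxidized precursor/b2); the remaining printed
values annotate within tolerance but are not forced to equal theory.

## Digestion

Trypsin specificity is the canonical rule: cleave C-terminal to K or R unless
the next residue is P, with no further exceptions (some rule sets add
W-K-P/M-R-P exceptions; they are deliberately omitted, which is why cleavage
is implemented directly rather than through a library digest function).
Coordinates are 1-based inclusive. Products with up to `max_missed` missed
cleavages are enumerated as concatenations of consecutive fully-cleaved
segments, ordered by start then length. Candidate selection keeps peptides
in a length window, optionally requires a C-terminal lysine (the taggable
ε-amine), flags methionine as oxidation-prone rather than excluding it — an
oxidation-stable Met peptide is a legitimate target — and scores uniqueness
as an exact substring count of 1 across a supplied FASTA set (no I/L
collapsing; that would be a config-level extension).

## Chromatogram simulation

A trace is `baseline + amount · response_factor · N(t; rt, σ) + ε` with `N`
the unit-area Gaussian kernel and ε i.i.d. Normal(0, noise_sd), sampled at a
fixed interval; `amount · response_factor` is therefore the peak *area*, and
the noiseless apex is that area divided by σ√(2π). Defaults (rt 300 s,
σ 5 s, 1 Hz sampling, 600 s duration, baseline 10, noise SD 1) describe a
generic unit-resolution MRM channel; none of them is calibrated to a real
instrument, which is also why absolute detection limits are explicitly out of
scope — only *ratios* of detection limits between response factors are
meaningful here.

S/N is estimated as (apex − baseline)/noise with the baseline the median and
the noise 1.4826 × MAD of the out-of-window points (robust to the peak tail
leaking into the baseline region). The apex is the in-window maximum of a
3-point moving average: with the raw maximum, the max-order statistic of the
window noise both fires on blanks (~4–5% at a 3:1 threshold) and adds an
amount-independent bonus that biases a fitted response slope; the light
smoothing removes both effects at a negligible (~1.3%) attenuation of the
true apex. A noiseless trace has zero MAD and raises "noise indeterminate"
rather than returning an infinite ratio. Detection is S/N ≥ 3, the
conventional limit-of-detection criterion.

The LOD of a descending dilution series is the smallest amount at which all
replicates (default 3) are detected, with every larger amount also fully
detected; the choice of an all-replicates rule is a documented convention, as
is the ±3σ peak window. For calibration fits the apex is read at the known
retention time (`apex_at`) instead of the window maximum, keeping the
amount→apex slope estimator unbiased; fits are ordinary least squares.

## Diagnostic statistics

Given TP/FP/TN/FN with n₁ = TP + FN diseased and n₀ = TN + FP non-diseased:
sensitivity TP/n₁, specificity TN/n₀, PLR = sens/(1 − spec),
NLR = (1 − sens)/spec, prevalence n₁/n, PPV = TP/(TP + FP),
NPV = TN/(TN + FN), accuracy (TP + TN)/n. Each statistic uses the CI method
standard for it:

* Clopper–Pearson exact beta-quantile intervals for the four binomial
  proportions, with the degenerate bounds pinned at 0 and 1;
* Simel's log method for likelihood ratios,
  exp(ln LR ± z·SE), SE(ln PLR) = √(1/TP − 1/n₁ + 1/FP − 1/n₀) and
  SE(ln NLR) = √(1/FN − 1/n₁ + 1/TN − 1/n₀);
* Mercaldo's logit method for predictive values,
  var(logit PPV) = (1 − sens)/(sens·n₁) + spec/((1 − spec)·n₀) and
  var(logit NPV) = sens/((1 − sens)·n₁) + (1 − spec)/(spec·n₀), with a term
  whose numerator rate is zero dropping out.

z is 1.96 exactly (not Φ⁻¹(0.975) ≈ 1.959964) at the 95% level — the
convention of the clinical calculators whose output these tables follow; the
two choices differ in the second decimal of one bound in the reference
tables, and 1.96 reproduces every printed bound. Statistics or intervals
that a zero cell leaves undefined (PLR when FP = 0, a CI for a predictive
value of exactly 0 or 1) are rendered as blank cells, never as infinity.

ELISA percent change is round(100·(end − begin)/begin) to the nearest
integer, half away from zero; it is undefined when the starting level is
undetectable, missing or zero, or the final level is missing. Concentration
unit labels are carried as metadata only — no unit conversion is attempted.

## Synthetic cohort

The generator draws disease status Bernoulli(prevalence), then per follow-up
week a screening call Bernoulli(sensitivity) for diseased and
Bernoulli(1 − specificity) for non-diseased subjects, and paired log-normal
assay concentrations per subject with group-specific log-mean/log-sd and a
detection floor (default 0.05 concentration units, just below the smallest
printed reference level of 0.017) under which a reading becomes
`undetectable`. Defaults mirror the reference study conditions: 28 subjects,
prevalence 0.25, weeks 11/24/36 with call rates (1/7, 1), (6/7, 1),
(6/7, 19/21), and identical assay distributions in both groups (log-mean
−0.7, log-sd 1.0, i.e. levels mostly 0.05–2 ng/mL) since the assay showed no
group difference. One `numpy` Generator seeded per cohort drives all draws;
the CSV writer formats concentrations at 3 dp so equal seeds give
byte-identical files.

What the generator does *not* emulate: gestational covariates and blood
pressure trajectories, within-subject correlation of calls across weeks
(calls are conditionally independent given status), assay measurement error
structure beyond log-normality, and dropout. Passing parameter-recovery
tests therefore show the estimator pipeline is correct on data satisfying
the model, not that the model captures every feature of a real cohort.

## Problem sizes used in tests

Property suites use 1,000 random peptides for mass-identity checks, 200
random proteins for digestion invariants, 200 seeds for Monte-Carlo S/N
distributions, 100 seeds for slope-recovery, 10,000 binomial draws for
Clopper–Pearson coverage at n = 28, and cohorts of 2,800 subjects for
rate recovery — sizes at which every Monte-Carlo check is comfortably
stable while the whole suite stays fast.

## Known limitations

Only b/y fragments and a single reporter per tag are modeled (no a/c/x/z
ions, neutral losses, isotope envelopes or average masses); collision-energy
and retention-time prediction are out of scope; the simulator's absolute
scales are arbitrary; diagnostic evaluation assumes a single 2×2 table per
timepoint with complete outcome data.
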