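# Methods

## The assay being modeled

The pipeline targets 384-well reporter screens in which androgen receptor
(AR) homodimerization reconstitutes a split luciferase, so agonists produce
a gain of luminescent signal and antagonists (co-administered with a
saturating synthetic androgen) a loss of signal. Because any insult that
kills cells also extinguishes luminescence, antagonist mode is paired with
a post-hoc resazurin viability read of the same physical plate, and hit
calling must separate genuine receptor antagonism from cytotoxic
signal loss. A metabolic retrofit retests the chemical set under twelve
transfection "biogroups" — mock, β-galactosidase, and ten human CYP
enzymes — so that CYP-formed metabolites can reveal themselves as gained,
lost, or potency-shifted activity.

## Normalization and thresholds

Plate statistics are computed per plate from raw signals. `bval` is the
median signal over the union of each test chemical's two lowest tested
concentrations (not the vehicle wells — this makes the baseline robust to a
plate's DMSO placement and is how the assay family defines it); `pval` is
the median of the ≥ 4 positive-control wells at the maximally effective
concentration (MEC). Agonist responses are `log2(RLU/bval)`; antagonist
and viability responses are `100·(RLU − bval)/(pval − bval)`. For the
viability read the anchor control is the cytotoxicity positive control
(full kill), so a viability response of v% means v% loss of viability.
Both maps are invariant to a per-plate gain, which is why plate-to-plate
detector drift needs no further correction.

`bmad` — the experiment-wide scaled median absolute deviation of
normalized vehicle responses, one per mode — is the unit of the activity
thresholds (5× for agonist, 3× for antagonist and viability). The MAD
carries the Gaussian consistency constant 1.4826 by default (the R `mad`
convention of this assay family's tooling; configurable). Vehicle wells in
agonist mode are normalized with the same plate `bval` as test wells,
since only one `bval` exists per plate. Modes are never pooled: the
agonist bmad is in log2 units, the antagonist/viability bmads in percent.
A viability-specific bmad is kept separately and falls back to the
antagonist value when no viability vehicle wells exist.

## Plate QC

`rZ' = 1 − 3(pmad + dmad)/|pmed − dmed|` on raw signals, using the MEC
positive-control wells and the vehicle wells. It is ≤ 1, equals 1 only at
zero variability, and is invariant to a common gain. Coincident medians
make it undefined; a −∞ sentinel plus warning is returned rather than an
exception so campaign tabulation survives a dead plate. For ranking
reporter constructs, per-concentration rZ' values are summed
(`cumulative_zprime`); the per-concentration groups may have as few as two
wells. Campaign summaries report the median per-plate rZ'.

## Hill fitting

The 3-parameter Hill model with bottom fixed at zero is fit by
`scipy.optimize.least_squares` (trf) on well-level responses — all
replicates, not per-concentration medians, so replicate information is not
discarded; a `use_medians` switch restores the median-fitting variant.
Box constraints follow qHTS convention: slope ∈ [0.3, 8]; log10 AC50
within [min tested − 2, max tested + 0.5]; top ≤ 3× the largest observed
response (with a 10⁻³ floor so null series collapse to top ≈ 0 rather than
chasing noise). Initialization is data-driven (top₀ = max median; AC50₀ =
concentration whose median is nearest top₀/2; slope₀ = 1.2) plus four
jittered restarts from a fixed seed, making fits deterministic. The best
start by residual sum of squares is reported; if no start converges the
parameters are still returned with `converged = False`, and downstream
calling defers rather than aborts. At least 4 distinct concentrations are
required. Fits are checked in the test suite against a dense lattice
search over the same parameter box.

## Hit calling and cytotoxicity gating

Threshold comparisons are strict (`>`), the log-separation test inclusive
(`≥ 0.5`), exactly as the rules are stated for this assay family. A
chemical is "also cytotoxic" when its viability series is itself a 3×bmad
hit using the viability bmad; only then is the 0.5-log10 (3.16-fold)
separation between cytotoxicity and antagonist AC50s demanded. Inactive
and confounded calls carry no AC50. The 2.5 log10 µM placeholder for
inactive chemicals exists only in the cross-assay potency comparison,
never in the calls themselves, because it is a plotting convention
(≈ 316 µM, beyond the tested range), not an estimate.

## CYP shift classification

The reference potency for a chemical is the median log10 AC50 across the
biogroups in which it is active when those form a majority of all tested
biogroups, otherwise the active members of the mock/Bgal pair. The
mock/Bgal consensus call decides gained/lost activity; on a mock–Bgal
split the mock (no-RNA) condition decides, it being the least perturbed.
`fold_shift = reference AC50 / biogroup AC50` (> 1 means more potent in
the biogroup); the default label cutoff is 2-fold with a minimum 0.3-log10
magnitude, the smallest shift treated as meaningful in this assay class,
and is configurable. Gained or lost calls within one bmad of the threshold
are annotated `marginal`, since a hair's-width threshold crossing is weak
evidence of metabolism. No significance test is attached — the screen has
three replicate experiments, too few for a useful per-chemical test — so
interpretation of marginal shifts is left to the user.

## Reference scoring

The packaged truth tables list reference chemicals with curated classes
(strong/moderate/weak/inactive) and the binary calls of four assay
variants per mode; "NT" rows are excluded from that assay's counts. The
footnoted active/inactive totals of the source tables disagree with their
printed rows in one case; the fixtures encode the printed rows, which are
what the printed metrics derive from. Sensitivity, specificity and
balanced accuracy are computed from unrounded fractions and rounded
half-away-from-zero to whole percent for reporting — the unique rounding
rule consistent with every printed cell (62.5 → 63, 93.75 → 94,
72.69 → 73).

## Synthetic campaigns

The generator forward-simulates the plate design: 8 DMSO wells, a 12-point
positive-control titration with 4 MEC replicates, a 12-point cytotox
control on antagonist plates, 11-point half-log test titrations from
99.9 µM (the printed bounds of the source assay's range are internally
inconsistent between text and figure captions; both are reachable through
`conc_top_uM`/`dilution_factor`), three independent experiments, and a
viability read sharing the antagonist plate's id and well labels. Agonist
signal is `baseline · 2^hill(c)`; antagonist signal interpolates between
the stimulated level (baseline × 75 by default, matching the
positive-control fold response) and the unstimulated floor, then is
multiplied by the viability fraction — the cytotoxic burn-down that the
gating rule exists to catch. Noise is multiplicative lognormal with
median 1 (so median-based plate statistics are unbiased) and CV 0.10 by
default, a typical luminescence plate CV; `noise_cv = 0` reproduces the
noiseless model bit-exactly. One RNG stream per call, seeded from
`SimConfig.seed`, makes output byte-identical across reruns. CYP modifiers
divide the AC50 by a potency multiplier and scale the top by an efficacy
multiplier, applied to agonist and antagonist truths; cytotoxicity is left
unmodified (modifiers are phenomenological, not kinetic).

What the simulator does *not* emulate: spatial plate effects (edge wells,
dispensing gradients), signal drift within a read, receptor-level
pharmacology (partial agonism, biphasic curves), DMSO or reagent
interactions, or the 2-h viability-reagent incubation offset in effective
concentration. Passing recovery tests therefore demonstrates that the
analysis inverts its own forward model under realistic noise — not that it
is robust to every artifact of real plates.

## Degenerate inputs and numerical choices

Zero raw signal in agonist mode has no log2 response; the well is flagged
and excluded from fitting. All-identical vehicle responses give bmad = 0
with a warning, and hit calling then refuses to run (the thresholds are
meaningless); noiseless simulations therefore require an explicit
thresholds override, as used in the test suite. Median ties need no
tie-break (numpy midpoint); the max-median summary breaks concentration
ties toward the lowest concentration. Problem sizes in the test suite and
acceptance script — 100-chemical single-mode campaigns, 20-chemical
three-biogroup campaigns, 6-chemical mixed campaigns — were chosen as the
smallest panels at which the stochastic recovery rates are stable
estimates.
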