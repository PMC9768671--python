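# Methods notes

This note records the models, defaults and design choices behind `asicca`,
in the spirit of a methods appendix: what is computed, under which
assumptions, and where the genuinely open choices were made.

## Hill dose-response models

All curve families are logistic on some axis and share one fitting core:

* **Activation.** `I(pH) = I_max / (1 + 10^((pH − pH50)·nH))`, increasing
  with acidity.  Fitting is done on the pH axis (not [H⁺]) with unweighted
  nonlinear least squares, midpoint and slope free, amplitude free unless
  fixed by the caller.
* **Steady-state desensitization (SSD).** The availability analogue,
  `1 / (1 + 10^((pHD50 − pH)·nH))`: 1 at alkaline conditioning pH, 0.5 at
  pHD₅₀.
* **Ca²⁺ inhibition at fixed pH.** The same logistic in log₁₀[Ca²⁺];
  IC₅₀ is returned in molar.
* **pH₅₀ vs [Ca²⁺].** A logistic in log₁₀[Ca²⁺] between two free pH₅₀
  asymptotes.  The functional form of this modulation curve is not uniquely
  dictated by theory; a free-asymptote log-logistic was chosen because it
  nests the limiting behaviours (alkaline plateau at vanishing Ca²⁺, acidic
  plateau at saturation) without asserting a binding mechanism.

Numerics: starts are data-driven (half-amplitude crossing plus the 25%/75%
quantiles of the x-range), a small multi-start loop guards against local
minima, bounds keep nH in (10⁻³, 50) and the midpoint within two spans of
the sampled range, and convergence is declared at 10⁻¹⁰ relative change of
the residual sum of squares.  Flat responses and fewer than four points are
rejected rather than fit.  Standard errors come from the linearized
covariance at the optimum.  Midpoints outside the sampled range ± 1 unit
(one decade for concentrations) are flagged, not rejected.

Per-cell versus pooled fitting: the default is one fit per cell followed by
group statistics of the midpoints.  Pooled fits (one fit over the union of
normalized points from several cells) exist for rundown-prone constructs
whose full curve cannot be measured in any single cell; they are flagged as
pooled and excluded from permutation testing because no per-cell midpoint
spread exists.

## Shift statistics and permutation inference

ΔpH₅₀ (or ΔpHD₅₀) is the difference of group means between the low- and
high-Ca²⁺ condition.  Its quoted uncertainty is the **sum** of the two
group standard deviations — deliberately conservative, since the two groups
come from different cells and no pairing exists.

The mutant-versus-WT test permutes construct labels **within each Ca²⁺
condition stratum**, with the difference of ΔpH₅₀ values as the statistic.
Rationale for this scheme (the choice was open): cells are unpaired across
conditions with unequal group sizes, so only the construct label is
exchangeable under the null, and stratification preserves the condition
structure exactly.  p-values are two-sided; Monte-Carlo runs use the
+1-corrected estimator (p = (#{|t*| ≥ |t|} + 1)/(B + 1)), which keeps the
test valid at any B, and a tie tolerance of 10⁻¹² guards against float
round-off when permuted statistics equal the observed one.  When the number
of distinct label assignments is at most the requested permutation count
the null is enumerated exhaustively and p is the exact tail fraction
(identity included, so p > 0 always).  The default is 10 000 permutations
and a mandatory seed.

Group comparisons of raw pH₅₀ values (ANOVA + Dunnett) are standard
procedures deliberately left to general statistics packages.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Cells.** Per-condition pH₅₀ and n_H drawn independently per cell from
  Normal distributions.  Wild-type defaults: pH₅₀ 7.48 ± 0.14 at 80 nM free
  Ca²⁺ and 6.14 ± 0.11 at 2 mM; n_H 2.08.  The cell-to-cell s.d. of n_H is
  not published; 0.15 was chosen as a typical inter-oocyte spread.  Maximal
  currents default to 4 ± 1 µA at 80 nM (published construct maxima are
  mostly above 2 µA) and are scaled by a pore-block factor of 0.65 at 2 mM,
  reproducing the ~35% inhibition of the pH 5 peak by millimolar Ca²⁺.
  I_max shares one standard-normal deviate across conditions within a cell,
  so the within-cell amplitude ratio concentrates at 0.65 while pH₅₀ draws
  stay independent.
* **Sweeps.** The ASIC component is driven by the *change* in Hill
  activation between conditioning and stimulation solution (each solution
  evaluated with the parameters of its own Ca²⁺ condition), which makes
  "no solution change → no current" exact and produces the low-Ca²⁺-induced
  current at constant pH 7.4 naturally.  Kinetics:
  `(1 − e^(−t/τ_act))·((1 − s)·e^(−t/τ_des) + s)` with τ_act = 0.2 s and
  τ_des = 2 s — values chosen (none are published) so the peak falls at
  ~0.48 s, within the first second after the solution change; `s` is the
  sustained fraction.  Sampling interval 20 ms; noise is additive Gaussian
  (default 5 nA on traces, 2% of the normalized response in datasets).
* **Endogenous current.** Oocyte connexin-hemichannel current:
  amplitude |N(93, 50)| nA, a slow saturating ramp `1 − e^(−t/τ)` with
  τ = 8 s (still visibly rising at 10 s), gated by acid inhibition
  (pH₅₀ N(5.41, 0.41), n_H 1.0 — the inhibition steepness is not published
  and 1.0 is the neutral choice) and suppressed by Ca²⁺ with IC₅₀ 100 µM.
* **Toy trajectories.** Each planted residue gets a dedicated Ca²⁺ ion that
  sits strictly within the contact cutoff in a Bernoulli(occupancy) subset
  of frames and is parked beyond twice the cutoff otherwise; residues are
  laid out 20 Å apart so plants cannot cross-contaminate.

Not emulated: single-channel behaviour, voltage dependence, series
resistance, solution-exchange kinetics, rundown trends within a recording,
ion residence-time correlation in trajectories.  Passing tests therefore
certify the *analysis* chain (feature extraction, fitting, inference) under
the assumed statistical structure, not the biophysics of real oocytes.

## Trace features and the endogenous-current QC rule

The baseline is the mean of all pre-switch samples; the peak is the
baseline-subtracted signed extremum within a configurable window after the
switch (default 0–2 s; peaks normally occur within the first second, the
window is kept wider for slow constructs).  The slow-component amplitude is
operationalized as the baseline-subtracted current at 3.5 s — after the
ASIC transient has largely decayed — matching the published measurement
convention for the endogenous current.  A cell passes QC iff every sweep at
stimulation pH ≥ 7.3 has |slow component| strictly below 5% of the cell's
maximal acid-induced peak; both thresholds are configurable, and the
boundary conventions (≥ for the pH, strict < for the fraction) follow the
printed rule.

## Contamination simulation

Mixture curves `(1 − f)·Hill_activation + f·Hill_acid_inhibition` are
normalized to their grid maximum and re-fit with the plain activation
equation (free amplitude, no baseline term).  Defaults: ASIC 7.48/2.08,
endogenous 5.41/1.0, pH grid 8.0 → 6.6 in 0.2 steps, spanning the wild-type
80 nM curve.  The grid is a genuinely open choice (the original grid is not
recorded); the apparent-parameter outputs move by a few hundredths of a pH
unit across plausible grids, which is why the package quotes them with that
caveat.  The result is insensitive to the assumed endogenous Hill
coefficient (< 0.01 pH units across n_H 0.5–2) because the endogenous term
is nearly flat over the ASIC activation range.  The admissible-amplitude
rule is plain arithmetic: an endogenous current A reaches contamination
fraction f at a total peak of A/f (0.93 µA for 93 nA at 10%).

## Chelator chemistry

Proton competition is folded into an apparent association constant
`K_app = K_CaL / (1 + Σ_i Π_{j≤i} K_Hj·[H⁺]^i)`; the 1:1 Ca:chelator mass
balance is then solved by bracketed root finding (residual < 10⁻¹⁰
relative), and recipe design inverts it in closed form.  Shipped constants
(EGTA, EDTA, citrate) are 25 °C / 0.1 M ionic-strength-class compilation
values and are overridable; ionic-strength and temperature corrections, and
multi-metal speciation beyond optional Mg²⁺, are out of scope.  Because
published chelator tables differ between calculators, correctness is
established by internal consistency (quadratic closed-form oracle,
forward–inverse round trips, monotonicity) rather than by matching any
specific calculator's totals.

## MD contact occupancy and protonation

A frame counts for a residue iff *any* Ca²⁺ is strictly within the cutoff
(default 2.5 Å) of one of the residue's designated side-chain atoms — Glu
OE1/OE2, Asp OD1/OD2, Asn OD1/ND2, Thr OG1, His ND1/NE2; backbone and
carbonyl oxygens are excluded, since the published "proximity" wording does
not pin the atom set and the polar side-chain tips are the chemically
sensible one.  Results are reported per (residue, subunit) with uniform
frame weighting; no correction is attempted for the tendency of ions to
remain bound once bound, so occupancies from short trajectories are
frequency statements, not affinities.  Protonation for a pH-mimicking
condition marks Glu/Asp protonated iff pKa ≥ pH (a side chain whose pKa
lies above ambient pH keeps its proton); the direction is configurable
because published phrasings of this rule are easy to invert, and His
residues are always recorded as neutral.  Site geometry reports minimum
side-chain O–O distances between residue copies, intra- and inter-subunit,
self-pairs skipped and missing atoms flagged.

## Pipeline and reproducibility

`run_pipeline` derives every stage seed from one root seed via
`SeedSequence` spawning, writes tidy CSVs with a fixed float format, and
records SHA-256 hashes in the manifest; identical config + seed gives
byte-identical tables.  Problem sizes in the shipped tests and in
`scripts/acceptance.py` (62 + 42 wild-type cells over 10 seeds; 1000 null
datasets of 6 + 6 cells for the type-I-error calibration; 10⁴-frame toy
trajectories) were chosen as the smallest sizes at which the targeted
statistics are stable to well within their quoted tolerances.

## Known limitations

* The generator draws pH₅₀ independently across conditions; any true
  within-cell correlation of pH₅₀ between Ca²⁺ conditions is not modelled
  (it would not bias the group ΔpH₅₀, only its variance).
* Pooled fits report no midpoint uncertainty comparable to per-cell s.d.
* The contamination defaults quantify the distortion for the wild-type
  80 nM curve specifically; other constructs need their own scenario.
* Apparent chelator constants ignore activity corrections; at ionic
  strengths far from 0.1 M the designed totals will drift accordingly.
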