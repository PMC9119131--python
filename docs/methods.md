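# Methods

## Observable model

A protein interconverts between two folded conformers, WT and SLIP, slowly
on the chemical-shift timescale, so each conformer's peaks integrate
separately.  The primary observable is the peak **volume** (heights are
accepted in the same column and treated identically); a per-peak response
factor multiplies each volume but cancels everywhere the analysis forms
volume ratios.  The package fixes the equilibrium direction as SLIP→WT:
`Keq = [WT]/[SLIP]`, so 50:50 means Keq = 1 and ΔG < 0 means WT is
favoured.  All concentrations are µM; energies kcal mol⁻¹, entropies
cal mol⁻¹ K⁻¹ (R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹).

## Population quantification

Percent WT at a condition is computed per residue pair (a WT and a SLIP
peak sharing a residue tag, e.g. `L391_WT`/`L391_SLIP`) as
`100·V_WT/(V_WT+V_SLIP)`, then averaged over pairs; the reported spread is
the standard deviation across pairs.  When no pairing exists, volumes are
summed per conformer and the spread is a jackknife over peaks.  Percentages
of exactly 0 or 100 (locked conformations, reported in population tables as
"<1"/">99") have no finite Keq and are treated as censored by the callers;
`keq_from_percent` refuses them.

## Van't Hoff analysis

`ln Keq` is regressed on `1/T` by unweighted ordinary least squares:
ΔH = −slope·R, ΔS = intercept·R.  Standard errors come from the linear
fit.  `ΔG(T) = ΔH − T·ΔS/1000` (explicit kcal/cal bridge); the headline
temperature is 298 K (pass 298.15 if wanted).  Above ~303 K this system's
apparent equilibrium flattens (aggregation), so fitting uses a linear
region: either every temperature at or below an explicit cutoff
(default 303 K), or `auto`, which grows a contiguous low-temperature window
(≥ 3 points) and keeps the window maximising r², preferring the widest
window on ties — perfectly linear data keep their full range, plateau
points are dropped.  Heat-capacity (curved) van't Hoff fits are out of
scope.

## Four-state binding model

States: WT·L ⇌ WT + L, SLIP·L ⇌ SLIP + L, WT ⇌ SLIP, with
`keq_apo = [WT]/[SLIP]` (unbound), dissociation constants `kd_wt`,
`kd_slip`, and cycle closure `keq_bound = keq_apo·kd_slip/kd_wt`.  A
non-binding conformer is an explicit sentinel (`NON_BINDING`), not a large
float, to avoid overflow and document intent; `keq_bound` then returns the
sentinel with a warning.  Solving for a given total protein and ligand is a
1-D root-find on free ligand `L` over `[0, l_total]` — the ligand balance
is strictly increasing in `L` with a guaranteed sign change, so Brent's
method converges unconditionally — followed by closed-form
back-substitution.  The solver is deterministic; residual tolerance is
1e−10 relative to the totals (both mass balances are verified to 1e−9 in
tests against an independent plain-bisection oracle).

## Titration inversion and isotherm fit

Only peaks flagged `unperturbed` (no chemical-shift change on ligand
addition) enter the scaling; in slow exchange their volumes report each
conformer's total (bound + unbound) concentration.  Per-peak volume ratios
against the zero-ligand reference are averaged to give the scale factors of
the WT and SLIP pools.  The inversion
`C_WT,B = C_WT,T − keq_apo·C_SLIP` generalises the equal-population
special case (`keq_apo = 1`, where it reduces to a plain difference) to
variants whose apo ratio is not 50:50.  Negative inversions (noise) are
clipped to 0 with a warning rather than dropped, keeping the ligand grid
intact.  The isotherm `Bmax·CL/(Kd+CL)` is fit by bounded nonlinear least
squares (`scipy.optimize.curve_fit`; start Kd = median nonzero CL,
Bmax = 1.2·max C_WT,B; bounds Kd ∈ (0, 10⁶] µM); errors are the
covariance square roots.  The methyl entry point runs the identical
machinery and exists so amide and methyl analyses are reported separately.

The invisible-state bound inverts the isotherm at the highest ligand
concentration: if an unobserved bound state can occupy at most a fraction
`f` of its conformer, then `Kd ≥ cl_max·(1−f)/f` (9 mM for f = 0.10 at
1000 µM).

## Synthetic data: the stated world

Generator defaults are the studied system's values: ΔH = 6.8 kcal mol⁻¹,
ΔS = 23.9 cal mol⁻¹ K⁻¹, temperature grid 278–303 K in 5 K steps
(optionally extended with a plateau above 303 K); keq_apo = 1,
kd_wt = 684 µM, SLIP non-binding, 200 µM protein, amide ligand grid
0–1000 µM; **5 peak pairs** per condition (the titration of record was
monitored on 10 peaks = 5 residue pairs).  Noise is mean-one multiplicative
lognormal with σ from the CV (volumes are positive and their errors scale
with size); an additive-Gaussian mode exists.  An optional
`broadened_bound_fraction` attenuates the bound-state contribution to WT
volumes, deliberately violating the unperturbed-peak premise to probe its
failure mode.  Identical config + seed → byte-identical tables.

### Two titration truths

`binding_mode` selects what "truth" the titration generator emits:

* `mass_action` (default): each point's state is solved exactly from the
  four-state equilibria, with ligand depletion and SLIP→WT re-supply.  The
  resulting `C_WT,B(CL_total)` is **not** a hyperbola in total ligand:
  fitting the single-site isotherm to it returns an apparent Kd well above
  the microscopic `kd_wt` (≈1670 µM vs 684 µM at the defaults) and a Bmax
  above the nominal WT pool.  Even against *free* ligand the binding curve
  is `p·L/(L + (1+1/keq_apo)·kd_wt)` — apparent Kd `(1+1/keq_apo)·kd_wt`,
  Bmax the *whole* protein pool — because bound WT is replenished from
  SLIP.  This bias is inherent to analysing conformationally coupled
  binding with Eq.-style isotherms and is inherited by any analysis of real
  data with this protocol.
* `isotherm`: `C_WT,B` follows `Bmax·CL/(kd_wt+CL)` in total ligand
  exactly, with Bmax equal to the apo WT pool and unbound WT held in the
  apo ratio with SLIP (ligand treated as in excess).  This is the stated
  world of the fitting model itself, so parameter-recovery tests that ask
  for exact (zero-noise) or tight (noisy) recovery run in this mode.

A green recovery test therefore establishes that the *pipeline* inverts and
fits correctly, not that the isotherm is the right microscopic model of a
coupled titration; the mass-action mode quantifies exactly how wrong the
hyperbola is.

### What the generator does not emulate

Lineshapes, chemical shifts, relaxation, exchange broadening (beyond the
crude bound-attenuation flag), baseline/phasing artefacts, aggregation
kinetics behind the >303 K plateau, and co-solvent effects.  Green tests
say nothing about peak picking or assignment, which are upstream of this
package.

## Numerical and design choices

* Unit system fixed at µM / kcal / cal; no converters in the core.
* Root-finding bracket `[0, l_total]` cannot lose the root; `rel_tol`
  defaults to 1e−10.
* Percent populations are invariant under uniform volume rescaling and
  under per-peak response factors (ratios cancel); tested as properties.
* Locked conformations are censored, not coerced to 0/100-derived Keq.
* The isotherm fit refuses series without a CL = 0 anchor or with no
  binding signal, rather than returning degenerate parameters.
* Fitting precision at the experimental noise level is limited: the
  inversion differences two ~100 µM scaled concentrations, so at 5% volume
  CV the median relative Kd error on the 0–1000 µM grid is ≈30% (5 pairs,
  500 replicates).  The error shrinks roughly linearly with the CV
  (≈6% at 1% CV), which the test suite asserts; quoting a Kd from a single
  such titration warrants an uncertainty estimate by replication or
  jackknife over peaks.

## Known limitations

Kinetics of interconversion are out of scope, as are multi-site or
cooperative binding, surface- vs core-site discrimination, fast-exchange
(chemical-shift-based) Kd estimation, and any spectral processing.
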