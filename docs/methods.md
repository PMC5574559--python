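# Methods

This note documents the model, the numerical choices and the design
decisions behind `laternula-deb`, and what the synthetic-data tests do and
do not demonstrate about real field data.

## Model and assumptions

The core is the standard DEB model for an isomorphic ectotherm: reserve
$E$, structure $V$, maturity $E_H$ and reproduction buffer $E_R$.
Assimilation scales with surface area ($L^2$) and the scaled functional
response $f$; mobilisation uses the standard isomorph closed form

$$\dot p_C = \frac{E}{V}\,\frac{[E_G]\dot v L^2 + [\dot p_M] V}{[E_G] + \kappa E/V},$$

which is the unique expression consistent with the reserve relaxation
equation $de/dt = (f-e)\dot v_T/L$ and with the weak-homeostasis
assumption. The $\kappa$-rule splits $\dot p_C$ between the soma and the
maturity/reproduction branch; birth (onset of feeding) and puberty (onset
of gametogenesis) are maturity thresholds $E_H^b$ and $E_H^p$.

Key simplifications:

- **Isomorphy, no metabolic acceleration.** The shipped assimilation and
  conductance values are taken as the operative post-metamorphic rates;
  the D-larva differs from the adult only through its own shape
  coefficient ($\delta_{M.lrv}$ = 7.227, applied solely to convert the
  structural length at birth into a physical D-larva shell length). With
  this reading the compound identities reproduce the reference ultimate
  sizes without an acceleration factor.
- **Cold-side temperature response only.** The Arrhenius correction uses
  the three-parameter lower-boundary form; no upper boundary is modelled
  because no warm-side data exist for this species.
- **Starvation rules.** When $\kappa \dot p_C < [\dot p_M]V$ the deficit is
  paid first from the reproduction/maturation flux and then from the
  reproduction buffer; structure never shrinks and gonad accretion halts.
  These rules are a conservative reading of maintenance priority; tissue
  resorption beyond the gonad is not modelled.
- **Reproduction buffer = gonad.** Gonad AFDW is $\rho_E E_R$. During a
  spawning window (default 15 December – 31 March) a configurable fraction
  (default one half) of the buffer present at onset is released following
  a logistic schedule whose default midpoint is the window centre and
  whose default steepness places 5–95% of the release inside the window;
  the current reproduction flux is shed directly rather than accumulated,
  and the unreleased remainder is retained unchanged for later seasons.

## Parameters

All rates are stated at $T_{ref}$ = 273.15 K; internal units are J, cm, g
AFDW, days, kelvin. The shipped file carries the reference set for
*L. elliptica*; everything derived ($E_m$, $L_m$, $k_M$) is recomputed,
never stored. Two parameters are conventions rather than measurements:
$\kappa_R$ (reproduction efficiency, default 0.95) and the GSI wet:dry
factors (body 6.0, gonad 4.79), the latter calibrated once so that a
full-year accumulation at the Marian Cove food level and 272.7 K yields a
gonadosomatic index of 0.21; GSI magnitudes are therefore indicative only.
The respiration proxy sums maintenance plus growth overhead (fraction
$1-\kappa_G$, default 0.2) and optionally an assimilation overhead; the
O₂ conversion is a single configurable oxycalorific scalar (default
16.4 J per mg O₂, from the reserve chemical potential of 550 kJ mol⁻¹ with
a standard stoichiometry). Only proportionality of this proxy is relied
on anywhere.

## Numerics

- ODE driver: LSODA with rtol 1e-8/atol 1e-10; maturity thresholds located
  by the solver's event root-finding with integration restart, so the
  switch in the equations stays sharp.
- The reproduction-buffer drain ramps to zero over the last joule of
  buffer, keeping the right-hand side continuous at $E_R = 0$ (a hard
  clamp makes the stepper chatter at the boundary).
- Embryo integration starts at $V_0 = 10^{-12}$ cm³ with $E_H = 0$; early
  growth is linear in $L$, so the start volume only shifts the birth age
  by $O(V_0^{1/3})$. The initial egg reserve is solved by root bracketing
  so that the reserve density at birth equals the maternal food level
  (maternal-effect rule), to relative tolerance 1e-6.
- Forcing interpolation: temperature linear, food piecewise-constant per
  day.
- Inside the covariation loss, size-at-age uses the exact
  constant-environment reduction of the growth equation (von Bertalanffy
  form $dL/dt = r_B(fL_m - L)$ with $r_B = k_M g / 3(f+g)$, floored so
  structure never shrinks) with the maintenance-free closed-form birth
  length $V_b = \kappa E_H^b/((1-\kappa)[E_G])$ as anchor; both agree with
  the full integrator to better than 1e-5 relative (tested).

## Estimation

- **Arrhenius fit**: nonlinear least squares on the scaled-rate curve;
  starting values $T_A$ = 8000 K, $T_{AL}$ = 50000 K, $T_L$ = min(T) − 1.
  The boundary temperature is bounded above by min(T) + 1 K: the cold
  boundary cannot sit above the coldest assay temperature, and leaving it
  free lets the boundary term trade off against $T_A$. Even so the
  three-parameter curve is weakly identified at realistic noise — the
  reference fit itself carries a ±27% standard error on $T_A$ — so
  recovery claims are made on replicate averages, not single fits.
- **Shape fit**: weighted least squares on $W_d = (\delta_M L_w)^3$,
  linear in $\delta_M^3$, default weights $1/W_d^2$ (relative error);
  dispersion propagated from the slope.
- **Covariation method**: Nelder–Mead on transformed parameters (log for
  positive quantities, logit for fractions), minimising
  $\sum_d w_d\,\mathrm{mean}((pred-obs)^2/obs^2)$ plus weak quadratic
  pseudo-data pulls (default weight 0.1) toward prior values; maximum
  5000 evaluations, simplex tolerance 1e-6, one restart if the simplex
  collapses. Goodness of fit is reported as the mean absolute relative
  error over all points and per dataset. The relative weights of the
  datasets are not dictated by theory; defaults are 1 and all recovery
  statements in this package are simulation-based.

## Seasonal reconstruction

Per-individual scaled reserve is read from condition data as
$e = (W - d_V L^3)/(\rho_E E_m L^3)$ with $L = \delta_M \times$ shell
length — i.e. the AFDW in excess of structural mass, normalised by the
reserve capacity of that structure. (A literal "weight minus volume"
reading is dimensionally inconsistent; the conversion through $d_V$ and
$\rho_E$ is the unique reading consistent with the shipped conversion
constants and with reserve composing ≈65% of dry mass at $e$ = 1.)
Individual values may leave [0, 1] under noise and are retained.

The smoother is a cubic P-spline (B-spline basis, second-difference
penalty) whose penalty weight is solved by bisection so the effective
degrees of freedom equal the knot budget (default 8 per two seasonal
cycles, requiring at least that many sampling events); the 95% band comes
from the smoother's posterior covariance. Tying the budget to effective
degrees of freedom makes the nesting property exact: a larger budget never
increases the residual sum of squares.

Inversion to food uses one-day central differences (one-sided at the
ends); reconstructed $f$ is clipped to [0, 1] with pre-clip values kept.
The band maps the smoother band through the same relation. Flux and gonad
series evaluate the population over its empirical shell-length
distribution with a common daily $e(t)$; bands propagate smoother
uncertainty only, not inter-individual variance. Both a
standard-individual and a population-aggregated mode are provided, since
either convention is defensible for summarising mobilisation against
maintenance.

## Covariate link

Daily $f$ is averaged into the covariate record's periods and compared
across a fixed candidate set of Gaussian linear models (chlorophyll or POC
flux, lithogenic flux, their sums and interactions, single covariates,
intercept), ranked by maximum-likelihood AIC with likelihood-ratio tests
between nested pairs. Chlorophyll and POC are near-collinear proxies of
the same bloom signal and are never entered together.

## Synthetic data: what it emulates, and what passing tests show

The scenario generator emulates a Marian-Cove-like setting: temperature
272.7 ± 1.5 K peaking in early February; food pulsing from a winter floor
of $f$ = 0.15 to a summer peak of 0.40 around a mid-January bloom (60-day
width); monthly sampling of 20 individuals (shell length 6 ± 1 cm) over
two years; lognormal 10% CV mass noise and 0.05 cm length noise;
calibration bundles at the three site food levels (0.332, 0.384, 0.8)
including a respiration–temperature series for a standard 7.5 cm
individual. All randomness flows from one seed through numpy's PCG64
generator with crc32-keyed substreams, so outputs are bit-reproducible
across runs and platforms.

The covariate generator's default signal-to-noise (noise sd 0.02 on the
response, standardised-covariate coefficients 0.08 / −0.05 / 0.03) is
deliberately stronger than a field season would give: it is set so the
generating interaction structure is recoverable by AIC at n = 20 periods,
which is what the selection machinery is tested against. A weaker,
field-like signal (noise sd ≈ 0.11, selected-model R² around 0.45) is one
config knob away and is used only for qualitative calibration; at that
signal level no selection procedure reliably identifies an interaction
from 20 periods.

What the synthetic data does *not* contain: individual heterogeneity in
food experience, size-dependent sampling bias, within-event temperature
excursions, measurement covariance between length and mass, or any
attempt to mimic the actual historical field numbers. A green round-trip
(mean absolute error of reconstructed $f$ below 0.05) therefore shows the
pipeline is self-consistent at realistic noise, not that a particular
historical reconstruction is correct.

## Known limitations

- The embryo at the shipped parameters predicts birth at 18.9 d at
  274.15 K (maternal $f$ = 0.8), below the reference prediction of
  21.6 d; the discrepancy is consistent with an embryo running at
  (nearly) temperature-uncorrected rates or at a pre-acceleration
  conductance, neither of which can be reconstructed from the published
  parameter set alone. All length- and weight-linked predictions
  reproduce within 3%.
- Which food level drives the age-at-puberty prediction is ambiguous in
  the reference material; the package defaults to the Marian Cove level
  for size-linked rows (giving 533 d against the reference 557 d) and
  treats the comparison as soft.
- Reconstructed $f$ is a scaled quantity; without feeding and clearance
  rates it cannot be mapped to absolute food density.
- GSI depends on unspecified wet:dry conversions and is excluded from any
  hard comparison.
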