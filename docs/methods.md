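# Methods

`pampakit` analyses parallel artificial membrane permeability assay
(PAMPA) data: a lipid-coated filter separates a donor well (volume
V_d = 0.3 cm³) from an acceptor well (V_a = 0.2 cm³) across a filter of
area A = 0.2826 cm²; compounds cross only by passive diffusion. This
note records the models, the numerical choices, and what the synthetic
generator does and does not emulate.

## Effective permeability from mass balance

For a well sampled at time t with donor concentrations C_d(0), C_d(t)
and acceptor concentration C_a(t), the fraction of the dose still
recoverable from the two wells is

    S = V_a C_a(t) / (V_d C_d(0)) + C_d(t) / C_d(0),

and 1 − S is the membrane retention. The effective permeability is

    P_e = − V_a V_d / ((V_a + V_d) A (t − t_0)) · ln(1 − (V_a+V_d) C_a(t) / (V_d S C_d(0))),

the rate constant of the acceptor's exponential approach to the joint
equilibrium of the two wells, with t_0 = 1140 s the average steady-state
lag for the membrane to saturate. The conventional prefactor
2.303·log10 is treated as exactly ln: the rounded 2.303 would introduce
a 0.013% systematic bias and break exact round-tripping. Only
concentration ratios enter, so the concentration unit is arbitrary.

Quality flags instead of exceptions cover the degenerate inputs:
`no_transport` (C_a = 0, P_e = 0 exactly), `at_equilibrium` (log
argument ≤ 1e-12; so close to equilibrium that noise makes P_e
unidentifiable, so no finite value is reported), and
`mass_balance_violation` (S > 1.02). S in (1, 1.02] is attributed to
read noise and clipped to 1 with a warning. Sampling at t ≤ t_0 is a
hard error. Replicate wells may be aggregated to mean ± SD; aggregation
happens *after* the P_e transform.

`forward_concentrations` is the exact closed-form inverse: the retained
fraction is taken up at t_0 and the wells then relax with rate
k = P_e·A·(V_a+V_d)/(V_a·V_d). Round-tripping through the two functions
recovers P_e to ≲1e-11 relative over P_e ∈ [1e-8, 1e-4] cm/s,
retention ∈ [0, 0.9] and t ≤ 16 h. Near the P_e·t extreme (e.g.
1e-4 cm/s at 24 h) the acceptor sits within exp(−20) ≈ 2e-9 of
equilibrium and the subtraction 1 − C_a/C_eq is representable only to
~5e-8 relative, a double-precision limit of the concentration
interface, not of the algorithm; such wells are close to the
`at_equilibrium` flag anyway.

## pH-partition model with unstirred-water-layer correction

Only the un-ionized species permeates the membrane
(Henderson–Hasselbalch fraction), while the unstirred water layer (UWL)
adds a pH-independent series resistance:

    1/P_e = 1/P_u + (10^{±(pH − pKa)} + 1) / P_o,

'+' for acids, '−' for bases; P_o is the intrinsic membrane
permeability of the neutral form, P_u the UWL permeability. The model
assumes ionized species do not permeate, and that both P_o and P_u are
constant over the pH range; active and paracellular routes are out of
scope.

**Ampholytes.** For zwitterionic drugs the denominator gets one term per
ionizable centre:

    1/P_e = 1/P_u + (10^{−(pH − pKa_basic)} + 10^{+(pH − pKa_acidic)} + 1) / P_o.

This reduces to the monoprotic form when one pKa leaves the pH window
and is unimodal with its maximum exactly midway between the two pKa
values (norfloxacin, pKa 6.26/8.63: peak at pH 7.445, consistent with
the observed maxima near pH 7). For drugs tabulated with three pKa
values (amoxicillin: 2.6, 7.31, 9.53) the outermost pair bracketing the
experimental window is used, the lower as the acidic centre; this
places the fitted maximum at pH 6.07, nearest the observed peak at
pH 6.57. Monoprotic drugs tabulated with a second far-off pKa
(famotidine 7.24/11.19) keep the pKa nearest the window centre.

**Fitting.** Weighted least squares on the P_e scale,
w_i = 1/sd_i² when SDs are available (a printed SD of 0 borrows the
smallest positive SD of the profile), optimised over (log10 P_o,
log10 P_u) with `scipy.optimize.least_squares` (trf, bounds
[1e-9, 1] cm/s, Jacobian scaling, tolerances 1e-15) from a
deterministic start (P_u = 2·max P_e; P_o from the most-unionized
point) plus a coarse log-grid multistart. A reciprocal-space mode
(fit 1/P_e) exists for comparison but is not the default: it
over-weights the smallest, noisiest P_e values. UWL-limited profiles
(P_e ≈ P_u everywhere, e.g. metoprolol) identify only a lower bound on
P_o; the estimate is then reported at the upper bound and the fit is
judged by its predictions, not by P_o.

**A structural identifiability caveat.** The monoprotic model depends on
(P_o, P_u, pKa) only through 1/P_u + 1/P_o and 10^{∓pKa}/P_o, so a
*fitted* pKa is not separately identifiable: any (P_o', P_u', pKa')
preserving those two combinations predicts the identical curve. The
`fit_pKa` option is therefore useful only as a curve-shape refinement;
tests assert recovery of the identifiable combinations. With pKa fixed
from tabulated values (the default) both P_o and P_u are identifiable
whenever the profile spans the transition region.

## Correlation with human fraction absorbed

Pearson product-moment r and Spearman rank rho (mid-rank ties) are both
computed, with squares, on raw (P_e, %FA) values — %FA stays on the
printed percent scale, untransformed. On the packaged 16 h screen the
published correlation figures are reproduced by Pearson r (0.745,
0.750, 0.740 for C8/C10/C12 over all ten drugs; 0.932, 0.948, 0.955
after excluding amoxicillin, cimetidine and ranitidine, whose transport
is thought to be carrier-mediated). The exclusion analysis recomputes
both panels under identical settings and refuses unknown drug names.

## The sandwich simulator

A linear four-compartment model generates assay-like data with known
ground truth: donor and acceptor wells, and a membrane split into

* a **transport pool** (water-equivalent capacity
  φ·K·V_m, default φ = 0.2) exchanged with each well at interface
  permeability 2·P_e, so the quasi-steady series resistance equals
  P_e exactly;
* a **binding pool** ((1−φ)·K·V_m) exchanged with the transport pool at
  the slower binding permeability (default P_e/2), standing in for
  hydrogen-bond sequestration by the immobilised lipid.

K is the membrane/water partition ratio (default 50) and V_m the
physical membrane volume (default 0.01 cm³), so the whole membrane
holds K·V_m·C at equilibrium with wells at C. Nothing moves before
t_0; afterwards the state evolves by matrix exponential (exact for a
linear system; mass conserved to machine precision, and detailed
balance holds, so with K = 1 everything equilibrates to equal
concentrations).

A single well-mixed membrane pool was tried first and rejected: the
S-corrected P_e equation exactly compensates single-pool retention, and
across a wide (P_e, K, V_m) grid the apparent-P_e time course stayed
within ~1% of flat. The two-pool split decouples the early
transport-pool filling (which starves the acceptor and makes apparent
P_e rise over the first hours) from the slow persistent binding drain
(which, once the wells have nearly equalised, pulls harder on the
smaller acceptor well and makes apparent P_e decline). With the
defaults the apparent-P_e course on a 4–20 h grid rises ~25%, peaks at
16 h, and declines slightly — the parabola shape characteristic of
retentive membranes. With negligible capacity the model collapses onto
the closed-form two-compartment solution and the apparent P_e is
constant at the true value to ≲1e-5 %.

Read noise is multiplicative lognormal with the mean-one
parameterisation (σ² = ln(1 + cv²)), applied independently to each
measured concentration: UV quantification error scales with signal.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical parameters and seed give
byte-identical output.

**What the generator does not emulate:** inter-well systematic biases,
pH-dependent membrane integrity, solubility/precipitation limits,
cosolvent (DMSO) effects, evaporation, and any structure–permeability
relation — lipid chain length (C8/C10/C12) is only a label mapped to a
user-chosen true P_e per membrane. Tests passing on synthetic data
therefore validate the estimators under the stated kinetic and noise
model, not the chemistry of a real plate.

## Problem sizes and defaults used in the shipped analyses

The recovery study uses 9 pH points (4–10), triplicate wells, 5%
multiplicative noise and 200 replicate datasets — triplicates and the
5% scale mirror typical UV plate-reader practice; 200 replicates give
stable medians (≈1.2% for P_o, ≈2.5% for P_u). The round-trip grid is
5 × 5 × 5 (P_e × retention × time); the oracle grid 7 × 4 against an
RK45 integration at rtol 1e-12. All run in seconds on one core.

## Known limitations

* The ampholyte equation is a natural extension, not a fitted
  mechanism; zwitterion-specific permeation (ion-pair transport) is not
  modelled.
* Fitted P_o/P_u have no external reference values, so they are
  validated by synthetic recovery and by profile-shape properties only.
* The famotidine C12/pH 4.98 reference cell is a suspected misprint and
  is kept verbatim; it slightly inflates that profile's residuals.
* P_e values from wells at or past equilibrium are unrecoverable in
  principle; the flags make this explicit rather than extrapolating.
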