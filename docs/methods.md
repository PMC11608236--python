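# Methods

## Model

`swinecell` implements a deterministic ODE model of the Large-White swine
ventricular cardiomyocyte with 61 state variables: membrane potential,
ten ionic concentration / Ca²⁺-cycling variables (Na⁺, K⁺ and Ca²⁺ in
myoplasm and subsarcolemmal subspace, network and junctional SR Ca²⁺,
intracellular Cl⁻), Hodgkin–Huxley gates for I_Na (with
CaMKII-phosphorylated variants), I_NaL, I_to2, I_Kr, I_Ks and I_K1,
thirty-two Markov occupancies for the L-type Ca²⁺ channel, two SR-release
driver states, and the trapped-CaMKII fraction.

The backbone (fast/late Na⁺ currents, delayed rectifiers, inward
rectifier, NCX, Na⁺/K⁺-ATPase, background and pump currents, Ca²⁺
buffering and four-compartment Ca²⁺ cycling with CaMKII-regulated release
and uptake) follows the ORd human ventricular formulation with swine-refit
maximal conductances and ionic conditions (K⁺_o 4 mM, Cl⁻ included, MgATP
4 mM to match the pipette solution, cylindrical geometry 105 × 12 µm).
Two structural departures define the swine cell:

* **I_to2 instead of I_to1.** Swine lack the K⁺-carried transient outward
  current; phase-1 repolarization is carried by a Ca²⁺-activated Cl⁻
  current with a voltage-dependent activation gate (Boltzmann, V½ 10 mV)
  and a Ca²⁺-activation gate driven by subspace Ca²⁺, with a GHK Cl⁻
  driving force (Hund–Rudy lineage).
* **Markov L-type channel.** VDI and CDI are separate four-state loops
  {C, O, I1, I2} sharing the voltage-dependent activation transition.
  A channel conducts when its VDI loop is open and its CDI loop is not
  inactivated. The CDI entry rates are Hill functions of subspace Ca²⁺;
  with Ba²⁺ as charge carrier they are zero (VDI isolated).
  Four 8-state blocks are integrated: {WT, G406R} × {non-phosphorylated,
  CaMKII-phosphorylated}; phosphorylated blocks have VDI time constants
  slowed 2.5×, which yields Ca²⁺/CaMKII-dependent facilitation (peak
  I_CaL grows with pacing rate). The loops are built as generator
  matrices (columns sum to zero), so occupancy is conserved exactly at
  the derivative level. Detailed balance around each loop is not
  enforced, as in the parent empirical gating models.

### TS1 (G406R) phenotype

Timothy-syndrome type 1 introduces a second LTCC subpopulation (default
22 % of channels) whose VDI transitions O→I1 and C→I2 are slowed 20×
(factors 0.05). These two factors were chosen so that, with 100 %
mutated channels and Ba²⁺ carrier, the voltage dependence of inactivation
flattens to the qualitative shape reported for heterologously expressed
G406R channels (≈26 % current remaining after 1 s at +30 mV vs 0 % in
WT). Secondary remodeling scales linearly with the active mutated
fraction: G_Ks × (1 − 0.4·active_TS1·fraction/0.22) and I_to2 shifted
+20.7 mV with 5 % lower conductance under the same linear law, so gene
silencing of mutated channels relieves the remodeling proportionally.

CaMKII couples to the Na⁺ currents through Hill functions (n = 2,
K_m 0.03) of the trapped-CaMKII fraction — a slow integral of activity
chosen over the instantaneous active fraction because an instantaneous
coupling produced artifactual beat-to-beat alternans through the
INaL→APD→Ca→CaMKII loop. G_Na is scaled down (gain 0.3) and G_NaL up
(gain 4), reproducing the rate-dependent depression of the TS1 upstroke
velocity and an I_NaL increase that reaches ≈2× WT at 1–2 Hz; at 0.5 Hz
the differential is weaker than the experimental 2× (see Limitations).

## Parameters that matter

| parameter | value | units | role |
|---|---|---|---|
| `gna` | 100 | mS/µF | fast Na⁺ conductance (upstroke ~200 V/s) |
| `gnal` | 0.00629 | mS/µF | fitted so the 22 °C clamp end-pulse is −0.12 A/F |
| `thl` | 61.55 | ms | hL time constant at 37 °C; ×2^1.5 at 22 °C gives the fitted 175 ms |
| `gkr`, `gks` | 0.02, 0.07 | mS/µF | swine repolarization relies on I_Ks more than I_Kr |
| `iks_tau_scale` | 0.3 | – | faster swine I_Ks kinetics than the human parent |
| `gk1` | 0.10 | mS/µF | resting potential ≈ −96 mV at K⁺_o = 4 mM |
| `pca` | 1.35e-4 | cm/s | LTCC permeability (peak I_CaL ≈ −2.5 A/F) |
| `gto2` | 2e-7 | cm/s-scale | notch depth of the spike-notch-dome AP |
| `jup_vmax` | 0.0066 | mM/ms | SERCA Vmax; sets SR load (jSR 1.15 mM at 0.5 Hz) |
| `rel_km_cajsr` | 1.0 | mM | jSR load at half-maximal release gain |
| `frac_ts1` | 0.22 | – | G406R channel fraction (experimental estimate) |
| `ts1_*_slow` | 0.05 | – | G406R slowing of the two VDI transitions |
| `stim_amp/dur` | −18 / 3 | A/F, ms | ≈1.25× diastolic threshold (bisection helper available) |

Temperature protocols use a parameter transform: +4.3 / +4.7 mV per
10 °C on Na⁺-current activation/inactivation V½ and Q10 = 2 on their
time constants (reference 37 °C). τ_hL is stored as the 37 °C value and
scaled the same way, so the simulated 22 °C clamp reproduces the fitted
175 ms; the alternative reading (175 ms at 37 °C, no Q10, closer to the
parent model's 200 ms) was implemented and rejected because the
resulting plateau I_NaL destabilizes the reconstructed WT cell at
0.5 Hz.

## Numerical choices

* LSODA (`scipy.integrate.odeint`) with a numba-compiled right-hand
  side; default tolerances rtol 1e-10 / atol 1e-11, max step 1 ms.
  Desk-scale analyses (tests, scans, acceptance script) use rtol 1e-7 /
  atol 1e-9, which changes steady-state APD90 by ≪0.1 ms.
* Integration is piecewise per stimulus segment so the rectangular pulse
  never crosses a solver step; clamp protocols fix V per segment
  (dV/dt = 0), AP clamp integrates the imposed waveform's derivative so
  V follows it exactly.
* Recorded beats are sampled at 0.05 ms around the upstroke and 0.25 ms
  elsewhere; run-in beats are not recorded. Halving the grid changes
  APD90 by <0.5 ms.
* GHK singularities at V = 0 are guarded by clamping |V| ≥ ~2.7 nV.
* Packaged steady states (`swinecell/data/steady_states.json`) are the
  result of 800 s of pacing per phenotype and frequency (0.5/1/2 Hz,
  rtol 1e-8), shipped like the initial conditions of published cardiac
  models; analyses restart from them with a 25–60-beat re-equilibration.

## Detectors (operational definitions, all configurable)

* **Capture**: V exceeds 0 mV within 20 ms of the stimulus *and* the
  cell was excitable (V < −40 mV) at the stimulus; a depolarized,
  non-repolarized state therefore counts as failure, which makes 2:1
  patterns detectable.
* **EAD**: dV/dt > +0.02 mV/ms sustained ≥5 ms, between the APD20 time
  and 95 % repolarization, beginning later than 80 ms after the
  upstroke. The exclusion window separates true afterdepolarizations
  from the physiological notch-dome redevelopment of the swine AP.
* **Alternans**: strictly alternating APD90 differences >5 ms over the
  last ≤10 beats.
* **CaT amplitude** is reported in model units of 1e-4 mM (≈ the
  fluorescence-normalized scale of the experimental transients).
* APDx is measured from the time of maximal upstroke velocity; RMP is V
  immediately before the stimulus; the CaT baseline is the minimum of
  cytosolic Ca²⁺ in the 50 ms before the stimulus.

## Calibration machinery and synthetic data

Per-current gating fits and the global 14-parameter conductance/flux
optimization minimize `Σᵢ weightᵢ·Σ(Y_sim − Y_exp)²` with Nelder–Mead
(box constraints by reflection; failed simulations contribute a 1e12
penalty so the simplex retreats smoothly). Because the original
voltage-clamp and biomarker tables are laboratory data, the
`fixtures` module generates synthetic stand-ins with known ground truth:
Boltzmann activation/availability curves, noisy peak I-V relationships
of an idealized channel, and biomarker tables centred on the model's own
output. These exercise every fitting path and allow parameter-recovery
tests, but they do not carry the correlated sweep-to-sweep structure,
rundown, or leak artifacts of real recordings — passing the recovery
tests demonstrates correctness of the machinery, not fidelity of any
particular fitted value to swine biology.

The population analysis randomizes the same 14 parameters with lognormal
scaling factors (median 1, σ_ln = 0.2; ≈98 % of draws within 0.5–1.5×),
paces each member at 1 Hz, drops invalid members (alternans, loss of
1:1 capture, repolarization failure) from both X and Y, z-scores
column-wise and solves B = (XᵀX)⁻¹XᵀY. Desk-scale runs use n = 50
members and 60-beat re-equilibration from the packaged steady state;
shorter run-ins misclassify converging members as alternans-positive.

## Design choices where the design was open

* The two LTCC subpopulations duplicate the full Markov block rather
  than sharing states with scaled rates — subpopulations inactivate
  independently.
* Ba²⁺ mode zeroes the CDI entry rates and keeps the Ca²⁺ driving-force
  constant; availability and FRC summaries are normalized, so only the
  VDI kinetics matter for the quantities the protocol is used for.
* Ca²⁺ ripples are a sinusoidal multiplicative modulation of the release
  parameter bt with configurable latency, frequency, magnitude and
  window — the three knobs the procedure is defined by.
* The I_NaL-blockade "share of prolongation" is
  100·(APD90_TS1 − APD90_TS1+block)/(APD90_TS1 − APD90_WT) at matched
  steady pacing.
* Therapy benefit is summarized as the mean over three phenotype axes
  (APD90, max dV/dt, diastolic jSR Ca²⁺) of |treated − WT|/|TS1 − WT|;
  over-correction scores as badly as under-correction.

## Limitations

* The fitted parameter tables and the full equation listing of the
  original swine model were not available to this implementation; the
  parameterization was reconstructed from the parent models and
  calibrated only to the quantities printed in the main text (late-Na⁺
  clamp values, Ca²⁺ targets at 0.5 Hz, remodeling factors, cell
  geometry, solver settings). Model-emergent quantities therefore
  deviate: EAD/2:1 onsets in the mutant-fraction scan occur near 49/50 %
  instead of 26.6/27 %, and the LTCC-activation-shift EAD thresholds are
  several mV instead of sub-mV — this reconstruction carries a larger
  repolarization-reserve margin, although the orderings (EADs before
  2:1; TS1 more susceptible than WT) are preserved.
* The CaMKII→G_NaL coupling transfers the Ca²⁺-overload signal with a
  rate profile that underweights slow pacing: the I_NaL share of TS1
  prolongation comes out near zero at 0.5 Hz and far too large at 2 Hz
  (reference: 35 % and 16 %).
* In the scaled population, WT validity (≈98 %) is slightly below TS1
  validity (100 %), inverting the reference relation (100 % vs 89 %).
* The hERG-activator intervention (+42 mV inactivation shift, 2.277×
  G_Kr) over-corrects APD90 on this parameterization, displacing it from
  the top of the therapy ranking.
* CaT amplitude decreases with pacing rate above 1 Hz, whereas
  experimental transients typically grow; the CaMKII-facilitation
  balance is imperfect.
* As in the parent models, SR release is slaved to I_CaL magnitude, so
  diastolic RyR2 leak is negligible and spontaneous-release phenomena
  are out of scope; there is no PKA/β-adrenergic module and no tissue
  coupling.
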