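# swinecell

A computational model of the Large-White **swine ventricular
cardiomyocyte**, in wild type (WT) and Timothy-syndrome type 1 (TS1)
variants, for studying action-potential (AP) dynamics, Ca²⁺ handling,
arrhythmogenic mechanisms and candidate therapies at the single-cell
level. It is aimed at cardiac electrophysiologists and modelers who
need a large-mammal alternative to human/rodent ventricular models —
for in-silico drug trials, gene-silencing design, or as the cellular
unit of future tissue simulations.

## The model

The cell is a stiff system of **61 ODEs**: membrane potential V; Na⁺,
K⁺, Ca²⁺ and Cl⁻ concentrations over myoplasm, subsarcolemmal subspace
and two SR compartments; Hodgkin–Huxley gates for I_Na, I_NaL, I_to2,
I_Kr, I_Ks, I_K1; a Markov L-type Ca²⁺ channel; SR-release states and
CaMKII. Membrane charge balance is

    dV/dt = −(I_Na + I_NaL + I_to2 + I_CaL + I_Kr + I_Ks + I_K1
              + I_NaCa + I_NaK + backgrounds + I_stim)      [A/F]

Swine specifics: the transient outward current is the Ca²⁺-activated
Cl⁻ current **I_to2** (no I_to1 in pig); repolarization reserve leans on
I_Ks rather than I_Kr; and I_CaL is an 8-state **Markov channel** with
separate voltage-dependent (VDI) and Ca²⁺-dependent (CDI) inactivation
loops {C, O, I1, I2}. The TS1 phenotype (CACNA1C p.Gly406Arg) is a
second LTCC subpopulation — 22 % of channels by default — whose O→I1
and C→I2 VDI transitions are slowed 20×, plus secondary remodeling
(−40 % G_Ks; I_to2 +20.7 mV, −5 %) and CaMKII-mediated scaling of
G_Na (down) and G_NaL (up) driven by Ca²⁺ overload. Interventions
(gene silencing with allele-variable specificity, verapamil,
ICA-105574, mexiletine, ranolazine, CaMKII inhibition, selective I_NaL
block, LTCC activation shifts, imposed late-systolic Ca²⁺ ripples) are
pure parameter transforms that compose freely.

See `docs/methods.md` for equations provenance, detector definitions,
numerical choices and known limitations.

## Worked example

```python
import numpy as np, swinecell as sc
from swinecell import biomarkers, interventions as iv

wt = sc.wild_type()                         # calibrated 37 °C parameter set
ts1 = iv.make_ts1(wt)                       # 22 % G406R channels + remodeling

for name, params, pheno in [("WT", wt, "wt"), ("TS1", ts1, "ts1")]:
    p = params.replace(stim_period=1000.0)  # 1 Hz pacing
    tr = sc.run(p, n_beats=30, y0=sc.steady_state(pheno, 1.0),
                record_beats=3, rtol=1e-7, atol=1e-9)
    b = biomarkers.extract(tr, beats=2)
    jsr = tr.y[np.searchsorted(tr.t, tr.beat_starts[-1]), 8]
    print(f"{name}: APD90 {b.apd90:.0f} ms  dV/dt {b.dvdt_max:.0f} V/s  "
          f"CaT {b.cat_amp:.1f}  jSR {jsr:.2f} mM  {b.capture_ratio}")
```

prints

```
WT: APD90 321 ms  dV/dt 177 V/s  CaT 4.6  jSR 1.13 mM  1:1
TS1: APD90 353 ms  dV/dt 170 V/s  CaT 7.6  jSR 1.38 mM  1:1
```

i.e. at 1 Hz the TS1 myocyte shows the disease signature: AP
prolongation (+32 ms), reduced upstroke velocity, a larger Ca²⁺
transient (CaT amplitude in units of 10⁻⁴ mM) and junctional-SR Ca²⁺
overload (1.38 vs 1.13 mM), while still capturing 1:1.

The command line mirrors the library:

```bash
swinecell simulate --phenotype ts1 --freq 0.5 --duration 60 --out out/
swinecell clamp --current inal --holding -120 --sweeps="-30:-20:10" \
    --temperature 22 --out inal_sweeps.csv
swinecell population --phenotype wt --n 50 --seed 1 --out pop/
swinecell treat --phenotype ts1 --drug ica105574 --out rx/
```

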