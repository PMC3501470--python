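# hemosplit

Separation of continuous-wave fNIRS hemoglobin signals into a cerebral
**functional** component and a **systemic** (physiological) component, based
on the different ways the two couple oxy- and deoxyhemoglobin.

## The problem

CW-fNIRS measures changes in oxyhemoglobin (ΔHbO) and deoxyhemoglobin
(ΔHbR) through the scalp. Task execution evokes not only the cortical
hemodynamic response of interest but also global systemic fluctuations —
scalp blood flow, blood-pressure (Mayer) waves, cardiac pulsation,
posture-driven hyperemia — that contaminate the recording and can mimic
activation. Band-pass filtering and block averaging cannot remove
task-locked systemic changes.

The two sources have opposite hemodynamic signatures:

* **Functional** (capillary bed, neurovascular coupling): a flow-velocity
  increase washes out deoxygenated blood, so ΔHbR\_F = *k*\_F·ΔHbO\_F with
  *k*\_F < 0. A survey of published responses gives *k*\_F = −0.56 ± 0.12;
  the package default is **−0.6**.
* **Systemic** (arteries/arterioles/venules/veins, volume-capacity
  changes): both species scale with vessel volume, so
  ΔHbR\_S = *k*\_S·ΔHbO\_S with *k*\_S ≥ 0. For a compartment at oxygen
  saturation *S*, *k*\_S = (1 − *S*)/*S*: < 0.053 arterial (*S* > 0.95),
  ≈ 0.43 venous (*S* ≈ 0.70), 1.0 at *S* = 0.50.

Writing the observation as the mixture ΔHbO = ΔHbO\_F + ΔHbO\_S,
ΔHbR = *k*\_F·ΔHbO\_F + *k*\_S·ΔHbO\_S and inverting:

```
ΔHbO_F = (k_S·ΔHbO − ΔHbR) / (k_S − k_F)
ΔHbO_S = (ΔHbR − k_F·ΔHbO) / (k_S − k_F)
```

*k*\_F is treated as a physiological constant; *k*\_S varies with task and
vascular bed and is **estimated per channel** by enumerating candidates
over [0, 1] in steps of 0.01 and minimizing the histogram-based mutual
information between the two separated components — the two vascular
compartments are assumed statistically independent.

The package also provides the surrounding pipeline: modified Beer–Lambert
inversion of multi-wavelength attenuation changes, zero-phase filtering and
downsampling, block averaging, FFT peak analysis, a paired laterality
t-test, component correlation/rescaling, and a seeded synthetic-session
generator with exact ground truth for validation.

## Worked example

```python
from hemosplit import (SynthConfig, estimate_ks, generate_session,
                       separate_components, standard_designs)
from hemosplit.separation import ModalityCoefficients
from hemosplit.analysis import laterality_ttest

design = standard_designs("finger_tapping")   # 20 s rest + 5x(L,rest,R,rest)
sess = generate_session(design, SynthConfig(seed=7))

est = estimate_ks(sess.observed["Left"], k_f=-0.6)
print(f"k_s_hat = {est.k_s_hat:.2f}  (boundary: {est.at_boundary})")

pair = separate_components(sess.observed["Left"],
                           ModalityCoefficients(-0.6, est.k_s_hat))
res = laterality_ttest(pair.functional, design)
print(f"functional laterality t = {res.t:.2f} (df={res.df}), p = {res.p:.4f}")
res = laterality_ttest(pair.systemic, design)
print(f"systemic   laterality t = {res.t:.2f} (df={res.df}), p = {res.p:.4f}")
```

Output:

```
k_s_hat = 0.38  (boundary: False)
functional laterality t = -21.47 (df=4), p = 0.0000
systemic   laterality t = -0.24 (df=4), p = 0.8215
```

The session was generated with true *k*\_S = 0.40; the estimate lands two
grid steps away. The separated functional component of this left-hemisphere
channel responds almost exclusively to right-hand tapping (large negative
t for the left-minus-right contrast), while the systemic component — which
reacts to tapping of either hand — shows no laterality.

The same chain is available from the shell:

```
hemosplit simulate --design finger_tapping --seed 7 --out session/
hemosplit separate --in session/observed.csv --kf -0.6 \
    --out components.csv --mi-profile mi.csv
hemosplit analyze --in components.csv --design session/design.yaml \
    --op laterality --out report.csv
```

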