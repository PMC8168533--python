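# aslkid

Renal arterial-spin-labeling (ASL) perfusion analysis at desk scale:
digital kidney/tumor phantoms, forward simulation of multi-PLD pCASL
acquisitions, the quantification chain from raw control/label pairs to
renal-blood-flow maps, ROI summaries, and the test-retest and diagnostic
statistics used to evaluate perfusion as a preoperative marker of
microvascular invasion (MVI) in clear-cell renal cell carcinoma.

## Who this is for

ASL perfusion studies of the kidney rest on a chain of processing steps —
pairwise subtraction, motion screening, M0 normalization, T1 mapping,
kinetic-model inversion — followed by reproducibility (ICC) and diagnostic
(ROC, logistic) statistics. `aslkid` implements that chain as a tested
Python library driven by synthetic data with known ground truth, so every
stage can be validated exactly: quantifying a noise-free simulated session
recovers the phantom's perfusion to machine precision, and each statistic
is checked against an independent oracle.

## The model

The perfusion-weighted difference signal ΔM = control − label follows the
single-compartment continuous-labeling solution. With labeling duration τ,
arterial transit time Δt, tissue relaxation time T1, blood relaxation time
T1b, labeling efficiency α and t = PLD + τ:

```
ΔM(t) = 0                                                          t ≤ Δt
ΔM(t) = S · (1 − e^{−(t−Δt)/T1})                               Δt < t ≤ Δt+τ
ΔM(t) = S · e^{−(t−Δt−τ)/T1} · (1 − e^{−τ/T1})                     t > Δt+τ
S     = 2 α M0 (f/6000) T1 e^{−Δt/T1b}
```

ΔM is linear in perfusion f (ml/100 g/min), so single-PLD quantification is
the closed-form division f = (ΔM/M0) / ΔM(f=1, M0=1), evaluated per voxel
at the fitted T1 and per slice at the exact post-label delay that slice was
read out at (nominal PLD + slice position × slice readout time). T1 comes
from a two-parameter inversion-recovery fit S(TI) = A(1 − 2e^{−TI/T1}).
A joint (f, Δt) multi-PLD fit and the consensus one-compartment shortcut
formula are available as alternative modes.

On top sit the study statistics: paired t and ICC(2,1) for two-session
reproducibility, pooled-variance Student's t for MVI+/MVI− group
differences, empirical ROC with trapezoidal AUC and Youden-index cutoff,
sensitivity/specificity/PPV/NPV with Wilson intervals, and
maximum-likelihood logistic regression with separation detection.

## Worked example

```python
from aslkid import ReproStudyConfig, run_repro_study

report = run_repro_study(ReproStudyConfig(n_subjects=16, seed=0))
for key, entry in report["results"].items():
    print(key, round(entry["icc"], 3))
```

prints

```
cortex_pld500 0.997
cortex_pld1000 0.997
cortex_pld2000 0.983
medulla_pld500 0.908
medulla_pld1000 0.906
medulla_pld2000 0.765
```

Sixteen simulated volunteers are scanned twice; the ICC compares
between-subject perfusion variance with session-to-session measurement
error. The cortex (large difference signal, many voxels) reproduces almost
perfectly, while the medulla — whose difference signal is about four-fold
smaller at identical noise — agrees visibly less well, the same cortical vs
medullary contrast reported in renal ASL test-retest work. The `examples/`
directory has one narrative script per capability (phantom simulation,
quantification with motion rejection, the reproducibility study, the MVI
diagnostic study); each prints the numbers it computes with a note on what
they mean.

A thin CLI mirrors the stages:

```bash
aslkid simulate --noise-sd 50 --seed 1 --out session/
aslkid quantify --session session/ --out maps/
aslkid cohort --seed 1 --out cohort.csv
aslkid mvi --table cohort.csv --score solid_pld1 --out mvi/
aslkid repro --subjects 16 --out repro/
```

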