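# rsacoupling

Linear and nonlinear quantification of respiratory sinus arrhythmia (RSA)
from paired respiration and heart-rate-variability (HRV) recordings.

RSA is the modulation of heart rate in synchrony with breathing — the heart
accelerates on inhalation and decelerates on exhalation. Part of this
cardiorespiratory coupling is linear, but nonlinear respiratory influences
on HRV have been proposed as biomarkers in anesthesia, sleep apnea, and
heart failure. This package separates the two contributions.

## Method

Present HRV samples are predicted autoregressively from the L most recent
respiration samples x̄ₙ⁻ = [x(n−1), …, x(n−L)] with ε-support-vector
regression, solved in the dual:

    yₙ(x̄) = Σₙ (αₙ − αₙ*) K(x̄, x̄ₙ⁻) + b

Fitting once with the linear kernel K(u, v) = uᵀv and once with the RBF
kernel K(u, v) = exp(−‖u − v‖² / σ²) gives two in-sample predictions y_l and
y_k, and two explained-variance indices

    Pxl = (y_lᵀ y_l) / (yᵀ y)        Pxk = (y_kᵀ y_k) / (yᵀ y)

Pxl captures the linearly respiration-driven HRV variance; Pxk additionally
admits nonlinear (e.g. quadratic) coupling. Both are compared against the
classical orthogonal-subspace-projection reference Px, the variance fraction
retained when HRV is least-squares-projected onto the lagged-respiration
subspace Q (conceptually P = Q(QᵀQ)⁻¹Qᵀ).

Supporting machinery:

* **Preprocessing** — RR intervals → cubic-spline tachogram at 2 Hz,
  zero-phase 4th-order Butterworth band-pass (0.03–1 Hz), 5-min epochs,
  Welch PSD (Hamming, 40 s windows, 20 s overlap).
* **Model order** — L covers two periods of the representative respiratory
  frequency Fr, read off the respiration PSD (lowest local maximum of the
  90%-power band when ≥ 3 maxima exist, else the global maximum; clamped to
  ≥ 0.1 Hz).
* **Hyperparameters** — c = IQR(y)/1.349 (robust scale of the response),
  ε = c/10, and σ² maximizing the Shannon entropy of the kernel-matrix
  entries over a log grid.
* **Nonlinearity significance** — 24 multivariate IAAFT surrogate pairs per
  epoch (one shared random phase vector preserves the cross-spectrum; exact
  amplitude multisets per channel); the coupling is declared nonlinear when
  the original Pxk exceeds the surrogates' 95th quantile.
* **Simulation bench** — a coupled autoregressive pair with controllable
  linear (C1) and quadratic (C2) driving, for validating the indices.
* **Group statistics** — Friedman / Kruskal-Wallis with Bonferroni-corrected
  pairwise follow-ups.

## Worked example

Quantify a simulated mixed (linear + quadratic) coupling:

```python
import rsacoupling as rc

x1, x2 = rc.simulate_pair(rc.SimulationConfig(c1=0.8, c2=1.2, seed=3))
design = rc.build_design(x1, x2, L=16)
res = rc.coupling_indices(design)
print(f"Px={res.Px:.3f}  Pxl={res.Pxl:.3f}  Pxk={res.Pxk:.3f}")

verdict = rc.nonlinearity_test(x1.samples, x2.samples, fs=2.0, L=16,
                               n_surrogates=24, seed=5)
print(f"Pxk={verdict.pxk_original:.3f}  threshold={verdict.threshold:.3f}  "
      f"nonlinear={verdict.significant}")
```

prints

```
Px=0.705  Pxl=0.686  Pxk=0.735
Pxk=0.735  threshold=0.701  nonlinear=True
```

The projection and linear-kernel indices agree (≈ 0.69–0.70 of the HRV
variance is linearly explained), the RBF index is higher (0.735) because it
also captures the quadratic term, and the surrogate test confirms that this
excess is significant — the surrogates, which destroy nonlinear structure
while keeping the linear coupling, top out at 0.701.

The same analyses run from the shell: `rsa simulate`, `rsa quantify`,
`rsa surrogate-test`, `rsa compare`, `rsa make-fixtures` (see `--help`).

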