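# saxsconf

Small-angle X-ray scattering (SAXS) analysis of multi-domain protein
conformational change, built around the question the technique answers
best: *does a protein adopt a different overall shape in solution than in
its crystal?*  The package was written for the open/closed equilibrium of
cA₄-activated CRISPR ancillary nucleases (Can1-type enzymes, whose compact
crystal form buries the activator between two CARF domains), but every
component is generic.

It provides, as a library plus a `saxsconf` command-line tool:

* **Model-free invariants** — Guinier fit (`I(q) ≈ I(0)·exp(−q²R_g²/3)`
  with a self-consistent `q·R_g ≤ 1.3` window and curvature-based
  trimming), dimensionless Kratky curves `(qR_g)²·I/I(0)` vs `qR_g` with
  the globular reference point `(√3, 3/e)`, and the Porod volume
  `V_p = 2π²I(0)/∫q²I dq`.
* **P(r) inversion** — the Moore indirect Fourier transform,
  `p(r) = r·Σ aₙ sin(nπr/d_max)`, fitted by weighted linear least squares
  with F-test term selection, plus a d_max scan that scores reciprocal-space
  fit, P(r) negativity and real-vs-reciprocal R_g consistency.
* **Debye profiles from coordinates** — a one-bead-per-residue calculator,
  `I(q) = Σᵢⱼ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ)`, with residue electron-count form
  factors.
* **Restrained rigid-body sampling** — domains move as rigid groups under
  centre-of-mass windows of half-width `π/q_max` capped at `d_max`,
  clash and linker-continuity checks, uniform Metropolis-style exploration.
* **Ensemble fitting** — reduced χ² with analytic scale, best single-state
  selection and exact two-state non-negative-weight mixtures.
* **Structure comparison** — Kabsch superposition, sequence-independent
  iterative-trim Cα correspondence, ligand transplantation, per-domain
  B-factor summaries.
* **Nicking kinetics** — gel-lane normalisation and single-exponential
  fits `f(t) = A(1 − e^(−kt))` for single-turnover plasmid nicking.
* **Synthetic data** — two-state toy particles, noisy profiles and
  mixtures, and replicated time courses, all with known ground truth.

## Worked example

Generate a known-truth two-state dataset and analyse it end to end:

```python
import numpy as np, saxsconf as sx

toy = sx.make_two_state_toy(seed=7)          # closed + open bead particles
q = np.linspace(0.008, 0.11, 60)
apo = sx.simulate_profile(toy.open, q, noise_level=0.01, seed=107)

rep = sx.profile_report(apo)
print(rep["guinier"]["rg"], rep["dmax"])     # 38.86  108.81

fit = sx.conformational_fit(
    apo, toy.closed_model, toy.decomposition, dmax=rep["dmax"],
    n=600, seed=29, mobile_groups=("domain3",), scheme="calpha-uniform",
)
print(fit["ground_state_chi2"])                       # 13.33
print(fit["best_single_state"]["chi2"])               # 1.33
print(fit["best_single_state"]["displacements_A"])    # {'domain3': 29.4}
```

Reading the numbers: the measured curve has R_g ≈ 38.9 Å and
d_max ≈ 109 Å, far larger than the closed ground state (R_g ≈ 30 Å,
d_max ≈ 95 Å); fitting that closed structure directly is rejected
(χ² ≈ 13), while the restrained rigid-body ensemble contains an opened
conformation — terminal domain displaced ≈ 29 Å, close to the true 25 Å
hinge — that fits the data within noise (χ² ≈ 1.3).  This is the logic by
which an apo "open" state is inferred from SAXS when only the closed,
ligand-bound crystal structure exists.

The same analyses are available from the shell:

```sh
saxsconf simulate two-state --seed 7 --out-dir demo/
saxsconf invariants demo/apo.dat --out report.json --pr pr.tsv
saxsconf calc-profile demo/closed.pdb --out closed_calc.dat
saxsconf kinetics timecourse.tsv --out fit.json
```

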