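# ringising

Statistical analysis of nearest-neighbour conformational coupling in
homo-hexameric ring proteins, built around the KaiC A-loop switch of
the cyanobacterial circadian clock.

Single-particle cryo-EM classification can assign each subunit of a
hexamer one of two conformational states — A-loop **buried (Bu)** or
**exposed (Ex)** — plus an **undefined (Un)** call for unresolved
densities. This package provides the machinery to turn such
per-subunit state calls into a quantitative test of subunit–subunit
cooperativity:

- **Ring combinatorics** — the 2⁶ = 64 Bu/Ex rings reduce to 13
  conformational patterns under ring symmetry (degeneracies Ω_k,
  Σ Ω_k = 64), and the 64 AA/EE phosphorylation labelings reduce to 14
  arrangements under rotation; orbit enumeration is cross-checked by
  Burnside counting.
- **Ring Ising model** — spins S_i = ±1 on a 6-site periodic ring with
  Hamiltonian H(S) = −J Σ_⟨ij⟩ S_i S_j − B Σ_i S_i (k_BT = 1), pattern
  probabilities p(k) = Ω_k e^{−H_k}/Z, the independent-subunit binomial
  null P_k = Ω_k p^{n_k}(1−p)^{6−n_k}, the exact finite-ring pair
  correlation via the 2×2 transfer matrix with eigenvalues
  λ± = e^J cosh B ± (e^{2J} sinh²B + e^{−2J})^{1/2} and correlation
  length ξ = 1/ln(λ₊/λ₋), and the field-response (Hill coefficient)
  analysis.
- **Fitting** — joint R²-maximizing fits of (J, B_AA, B_EE) to two
  pure-mutant pattern distributions with profile uncertainty
  (R² ≥ 0.95 region); correlation-function fits; a mixed-composition
  model P_k = Σ_l q_l p_l(k) with arrangement weights q_l fitted on the
  14-simplex under a soft equal-composition constraint, a cross-coupling
  offset ΔJ for unlike neighbours, and the enrichment factor α.
- **Mask-overlap classifier** — Bu/Ex/Un calls for per-subunit density
  volumes from overlap intensities I_n = Σ_i D_{i,n} M_i against
  dilated reference masks (CCP4/MRC I/O via gemmi).
- **Synthetic data** — exact Boltzmann sampling of hexamer ensembles
  (pure and mixed composition), independent Un masking, study-scale
  presets, and separable synthetic volumes, so every stage is testable
  without any cryo-EM download.

## Worked example

Simulate the two phosphomimetic pure samples at study scale
(140,475 rings with 25.7% undefined calls; 371,557 rings with 18.2%),
tabulate the 13-pattern distributions, and fit the shared-coupling
Ising model:

```python
import ringising as ri

aa = ri.simulate_dataset(ri.preset("AA", seed=42))
ee = ri.simulate_dataset(ri.preset("EE", seed=43))
obs_aa, _ = ri.tabulate_patterns(aa)   # drops rings with any Un call
obs_ee, _ = ri.tabulate_patterns(ee)
fit = ri.fit_pure(obs_aa, obs_ee)
```

Output (seeds 42/43):

```
AA rings kept: 23687  EE rings kept: 111370
J = 0.141  (R2 >= 0.95 interval: [0.057, 0.225])
B_AA = 0.185  B_EE = -0.250  R2 = 0.9995
C~(x), AA: [1.     0.1351 0.0183 0.0038]
xi_AA = 0.50
DeltaH_AA = 0.37  DeltaH_EE = -0.50
```

The datasets were generated at J = 0.14, B_AA = 0.19, B_EE = −0.25;
the joint fit recovers them from the masked pattern counts alone. The
positive shared coupling means neighbouring subunits favour matching
conformations; the opposite-signed fields shift each mutant's
Bu⇄Ex balance, with single-subunit free-energy differences
ΔH = 2B. The short correlation length ξ ≈ 0.5 subunits confirms that
nearest-neighbour interactions dominate.

The same stages are scriptable from the shell:

```sh
ringising simulate --preset AA --seed 42 --out aa.tsv --counts-out counts_AA.tsv
ringising simulate --preset EE --seed 43 --out ee.tsv --counts-out counts_EE.tsv
ringising fit-pure --counts-aa counts_AA.tsv --counts-ee counts_EE.tsv
ringising correlate aa.tsv
```

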