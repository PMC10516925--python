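# Methods

## Model

Each subunit of a hexameric ring carries a spin S_i ∈ {+1 (exposed),
−1 (buried)}, i = 1..6 with periodic indexing (S_7 ≡ S_1). The energy
of a ring, in units of the effective thermal energy (β = 1
throughout), is

    H(S) = − Σ_⟨ij⟩ J_ij S_i S_j − Σ_i B(σ_i) S_i

with the six nearest-neighbour bonds counted once each. σ_i ∈ {0 (AA),
1 (EE)} is the subunit's phosphorylation label; B(0) = B_AA,
B(1) = B_EE; J_ij = J for like-labelled neighbours and J − ΔJ for
unlike ones (ΔJ = 0 unless fitted). J > 0 favours neighbouring
subunits adopting the same conformation; B > 0 favours the exposed
state, and the single-subunit free-energy difference between exposed
and buried is ΔH = 2B.

At equilibrium, the 64 ring configurations group into 13 patterns
under the dihedral symmetry of the ring (rotations + reflections),
each with degeneracy Ω_k (Σ Ω_k = 64) and a common energy H_k under
uniform labels, giving p(k) = Ω_k e^{−H_k} / Σ_k Ω_k e^{−H_k}. All
partition sums are evaluated in log space (log-sum-exp), stable for
|J|, |B| ≤ 5.

### Symmetry conventions

The 13-class reduction of conformational patterns corresponds to the
dihedral group; rotation-only reduction gives 14 classes. Both groups
are implemented and `build_patterns` accepts either; the dihedral
count is the default because it matches the published 13-pattern set
and its degeneracies. Phosphorylation arrangements use rotation-only
reduction, reproducing the published 14 classes. Patterns are ordered
by decreasing exposed count with lexicographic tie-breaks, which pins
pattern 3 to EEEEBB and pattern 4 to EEEBEB as in the published
ordering; the full mapping is exported by `ringising enumerate` so
users can remap. A stable hash of the pattern table is written to
every pipeline run log so a renumbering between versions is
detectable.

### Mixed composition

When labels are non-uniform, members of a pattern class differ in
energy, so the per-arrangement pattern probability p_l(k) is defined
as the Boltzmann sum over the class members:

    p_l(k) = Σ_{c ∈ class k} e^{−H_l(c)} / Σ_c e^{−H_l(c)} ,

which sums over all relative orientations of the pattern and the
arrangement (the classes discard absolute orientation) and reduces
exactly to the Ω_k e^{−H_k} form for uniform labels. This is one
consistent reading of an effective class energy; it is the convention
throughout. p_l(k) is invariant to the choice of representative of
arrangement l, because pattern classes are closed under the ring
symmetries. The population distribution is P_k = Σ_l q_l p_l(k) with
arrangement weights q_l on the 14-simplex.

## Correlation functions

The empirical pair correlation is
C(x) = ⟨S_{n,i} S_{n,i+x}⟩_{n,i} − ⟨S⟩², where ⟨S⟩ pools every
defined (non-Un) monomer and the pair average runs over all hexamers
and all site pairs (i, i+x mod 6) whose two members are both defined.
Lags 0..3 are reported (x and 6−x coincide on the ring); the
normalization is C̃(x) = C(x)/C(0). A dataset with zero conformational
variance (C(0) = 0) is rejected as degenerate.

The model correlation is evaluated **exactly** on the finite ring via
the 2×2 transfer matrix T = [[e^{J+B}, e^{−J}], [e^{−J}, e^{J−B}]]:
C(x) = Tr(Σ T^x Σ T^{6−x})/Tr(T⁶) − ⟨S⟩² in the eigenbasis, with
eigenvalues λ± = e^J cosh B ± (e^{2J} sinh²B + e^{−2J})^{1/2} and
correlation length ξ = 1/ln(λ₊/λ₋). The familiar two-exponential ring
decay

    C̃(x) = [e^{−x/ξ} + e^{−(6−x)/ξ}] / [1 + e^{−6/ξ}]

is exact only at B = 0; at B ≠ 0 it omits an x-independent term of
relative size ~(λ₊λ₋/λ₊²)⁶ (about 1e−6..1e−4 in the parameter range of
interest). It is provided separately as
`two_exponential_correlation`; the exact evaluator is what the tests
hold to 1e−10 against 64-state enumeration and what the correlation
fit uses. λ₋ = 0 at J = 0 (and λ₋ < 0 for J < 0); both are treated as
the ξ = 0 limit, with C̃(x) = 0 for 1 ≤ x ≤ 5.

## Fitting

**R² convention.** R² = 1 − SS_res/SS_tot on the concatenated
probability vectors (26 entries for a joint AA+EE fit), SS_tot about
the concatenated mean. Whether a count-weighted variant would be
preferable is data-dependent; only the probability-based form is
implemented, and it is stated here prominently so users can compare.

**Pure-sample fit.** (J, B_AA, B_EE) with J shared between datasets.
At fixed J the two fields decouple, so the profile R²(J) is computed
on a grid (J ∈ [0, 0.5], step 0.005) with exact scalar field
optimization at each node, then the best node is polished by
Nelder-Mead. Deterministic given the inputs. Uncertainty is the
profile region {θ : R²(θ) ≥ 0.95}, interpolated at the grid crossings;
fields are profiled the same way with J re-optimized. Note the
R² ≥ 0.95 interval does **not** shrink to zero with sample size: even
noise-free data has a finite R² ≥ 0.95 region (width ≈ 0.17 in J at
the study parameters), and sampling noise lowers the attainable R²,
narrowing the interval below its asymptote. The consistency property
that does hold — and is tested — is that the fitted Ĵ converges to the
generating value as n grows, and that the interval covers the truth at
the stated rate.

**Correlation fit.** Least squares of the exact ring C̃(x), x = 1..3,
over (J, per-dataset field), J shared. The correlation alone is even
in B and, on noisy data, nearly degenerate along a large-J/large-|B|
ridge, so it identifies neither the field's sign nor, robustly, the
coupling. The fit therefore accepts each dataset's pooled mean spin as
one additional residual (model ⟨S⟩ from exact enumeration minus
observed), which pins the field given J and fixes its sign; without
it, the fit returns |B| and confines the search to J ∈ [0, 0.5],
|B| ≤ 1.

**Mixed-composition fit.** With (J, B_AA, B_EE) frozen at the
pure-sample estimates, the weights minimize

    Σ_k (P_k(q) − P_k^obs)² + λ (f_EE(q) − ½)² ,   f_EE(q) = Σ_l q_l n_EE,l/6,

subject to Σ q_l = 1, 0 ≤ q_l ≤ 1. The quadratic composition penalty
(default λ = 0.1, the published operating point) is this package's
reading of the "approximately equal composition" constraint; a hard
constraint can be emulated with large λ. The objective is a convex QP
over the simplex, solved by SLSQP from a fixed multi-start list (the
two extreme scenarios, the barycenter, and seeded Dirichlet draws), so
results are deterministic; failure of every start raises rather than
returning silently. Fourteen weights against thirteen probabilities
are not identifiable: the contract is on the fitted P_k and f_EE, and
the CLI prints a non-uniqueness warning alongside q. Reference
scenarios: *no-mixing* puts mass only on the two pure arrangements;
*fully-mixed* is q_l = m_l ee^{n_EE,l}(1−ee)^{6−n_EE,l}. The
enrichment factor is α_l = q_l(fitted)/q_l(fully-mixed). The
cross-coupling offset is fitted one-dimensionally under fully-mixed
weights with J_cross = J − ΔJ, so ΔJ > 0 means a weakened AA–EE bond
(the sign convention is stated here because the printed value's sign
is ambiguous in its source).

**Hill coefficient.** The exposed-fraction response is
f_Ex(B) = (1 + ⟨S⟩(B))/2 by exact enumeration; the effective Hill
coefficient is the midpoint-slope ratio
n_H = f′(0; J)/f′(0; J=0) = Var_J(M)/6 (M = total spin), so
n_H(J=0) = 1 by construction and n_H increases with J. This
midpoint-slope definition is a convention of this package; only its
qualitative monotonicity (cooperativity sharpens the switch) is
asserted against external results.

## Synthetic data

The generator samples ring configurations **exactly** from the
Boltzmann distribution by inverse CDF over the enumerated 64-state
table (per drawn arrangement for mixed composition) — the state space
is tiny, so no MCMC is involved. Undefined calls are applied
independently per monomer at rate u, matching the randomness
assumption under which the expected fully-defined count is
n(1−u)⁶; an optional beta-binomial intraclass-correlation knob
clusters Un calls within rings for sensitivity analysis (default
off). One seed per dataset is split into independent child streams
(arrangement, configuration, masking) via `SeedSequence.spawn`.

Presets mirror the study conditions: AA (n = 140,475, u = 0.257),
EE (n = 371,557, u = 0.182), mixed (n = 175,284, u = 0.304 — not
printed directly; implied by the mixed sample's 19,858 fully-defined
rings via (19858/175284)^{1/6}). Default generator parameters are
J = 0.14, B_AA = 0.19, B_EE = −0.25.

What the generator does **not** emulate: cryo-EM image formation
(projection, CTF, alignment error), classification bias that depends
on a subunit's true state or on its neighbours, and any correlation
between Un calls and conformation. Passing recovery tests therefore
show that the estimators are correct under the model's own
assumptions — unbiased state calls with independent dropout — not
that those assumptions hold for any particular experimental dataset.

Synthetic volumes are 16³ grids with a Gaussian blob (amplitude 1,
width 2 voxels) at a fixed A-loop site: full strength for Bu, half
for Un, absent for Ex, plus i.i.d. Gaussian noise. They are separable
by construction and exercise the classifier's mechanics, not its
robustness to realistic density heterogeneity.

## Volume classifier

Reference volumes are averaged, binarized at a stated density
threshold, and dilated by 1 voxel (mask1) or 2 (mask2);
"in all directions" is read as the 26-connected cube structuring
element (6-connectivity available). A volume is Bu iff both overlap
intensities reach their lower cutoffs, Ex iff both fall at or below
their upper cutoffs, Un otherwise — borderline volumes are never
forced into Bu or Ex. The Bu/Ex cutoffs were set by visual inspection
in the original analysis and are not portable numbers; defaults here
are quantiles of the cohort's intensity distribution (tertiles absent
other information; when class prevalences are known, upper = 1 − f_Bu
and lower = f_Ex align the cutoffs with the cluster gaps), and cutoffs
may be expressed in units of σ (the density standard deviation within
the hexamer region, or the whole grid when no region mask is given),
which makes calls invariant under density rescaling. The 2σ/4σ display
levels used for visual audit are reported with every call.

## Numerical choices and degenerate inputs

- Partition sums: log-sum-exp throughout; distributions renormalized
  to machine precision.
- Optimizers: bounded scalar minimization (xatol 1e−7) for field
  profiles; Nelder-Mead polish (xatol 1e−8, fatol 1e−14); SLSQP
  (ftol 1e−14) for the simplex QP; `least_squares` (xtol/ftol/gtol
  1e−15) for correlation fits.
- Degenerate inputs raise: all-identical state calls (C(0) = 0),
  all-Un datasets, empty masks after thresholding, distributions off
  the simplex beyond 1e−9.
- Problem sizes in the default test run: recovery studies use the
  full study-scale ring counts (sampling is O(n) and fast); volume
  cohorts use tens to hundreds of 16³ grids.

## Known limitations

- Equilibrium statistics only; no kinetics of Bu⇄Ex switching.
- Nearest-neighbour couplings only; no longer-range terms.
- Ring size 6 is validated; other sizes are supported by the math but
  untested against any reference value.
- The q_l fit reports one point of a non-unique optimum set; only
  P_k(q) and f_EE are identified.
- The mask-overlap classifier assumes pre-extracted, aligned
  per-subunit volumes; no classification/refinement is performed.
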