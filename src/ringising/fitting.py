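"""Parameter estimation for the ring Ising model.

Pure-sample fits maximize the coefficient of determination R^2
between model and observed pattern probabilities, with the coupling J
shared between the AA and EE datasets and one local field per
dataset.  Uncertainty is the profile region where R^2 >= 0.95.
Mixed-sample fits estimate the arrangement weights q_l on the
14-simplex under a soft composition constraint, and optionally a
cross-coupling offset delta_J between unlike neighbours.

R^2 here is the standard coefficient of determination computed on the
concatenated probability vectors (26 entries for a joint AA+EE fit),
with SS_tot about the mean of the concatenated observed vector.  A
count-weighted variant is not implemented; users wanting chi-square
style weighting can pre-scale the vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .ising import (
    IsingParameters,
    PatternDistribution,
    CorrelationFunction,
    brute_force_distribution,
    closed_form_correlation,
    mean_spin as ising_mean_spin,
    pattern_distribution,
)
from .rings import PhosphoArrangement, build_arrangements

#: default search grids: J on [0, 0.5] and fields on [-1, 1], step 0.005
DEFAULT_J_GRID = np.round(np.arange(0.0, 0.5001, 0.005), 6)
DEFAULT_B_BOUNDS = (-1.0, 1.0)
R2_CUTOFF = 0.95


@dataclass
class FitResult:
    params: IsingParameters
    r_squared: float
    uncertainty: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)


@dataclass
class MixingWeights:
    """Weights q_l over the 14 phosphorylation arrangements."""

    q: np.ndarray
    lambda_weight: float = 0.0
    scenario: str = "free"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1:
            raise ValueError("q must be a vector")
        if np.any(self.q < -1e-9) or abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError("q must lie on the probability simplex")
        self.q = np.clip(self.q, 0.0, None)
        self.q = self.q / self.q.sum()

    @property
    def ee_fraction(self) -> float:
        """Overall fraction of EE monomers implied by q."""
        ee = np.array([a.ee_count for a in build_arrangements()], dtype=float)
        return float(self.q @ ee / 6.0)


def _concat(dists) -> np.ndarray:
    if isinstance(dists, PatternDistribution):
        dists = [dists]
    return np.concatenate([np.asarray(d.probabilities, dtype=float) for d in dists])


def r_squared(model, observed) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on concatenated vectors."""
    m, o = _concat(model), _concat(observed)
    if m.shape != o.shape:
        raise ValueError("model and observed distributions must align")
    ss_tot = ((o - o.mean()) ** 2).sum()
    if ss_tot < 1e-20:
        raise ValueError("observed vector has zero variance")
    return 1.0 - ((m - o) ** 2).sum() / ss_tot


def _ss_res_joint(J, b_aa, b_ee, obs):
    """Residual sum of squares of the joint AA+EE pattern fit."""
    obs_aa, obs_ee = obs
    m_aa = pattern_distribution(IsingParameters(J=J, B_AA=b_aa), labels="AA")
    m_ee = pattern_distribution(IsingParameters(J=J, B_EE=b_ee), labels="EE")
    return (
        ((m_aa.probabilities - obs_aa.probabilities) ** 2).sum()
        + ((m_ee.probabilities - obs_ee.probabilities) ** 2).sum()
    )


def _best_fields(J, obs_aa, obs_ee, bounds=DEFAULT_B_BOUNDS):
    """Optimal (B_AA, B_EE) at fixed J; the two fields decouple."""

    def ss_aa(b):
        m = pattern_distribution(IsingParameters(J=J, B_AA=b), labels="AA")
        return ((m.probabilities - obs_aa.probabilities) ** 2).sum()

    def ss_ee(b):
        m = pattern_distribution(IsingParameters(J=J, B_EE=b), labels="EE")
        return ((m.probabilities - obs_ee.probabilities) ** 2).sum()

    r_aa = optimize.minimize_scalar(ss_aa, bounds=bounds, method="bounded",
                                    options={"xatol": 1e-7})
    r_ee = optimize.minimize_scalar(ss_ee, bounds=bounds, method="bounded",
                                    options={"xatol": 1e-7})
    return r_aa.x, r_ee.x, r_aa.fun + r_ee.fun


def _joint_r2(ss_res, obs_aa, obs_ee):
    o = np.concatenate([obs_aa.probabilities, obs_ee.probabilities])
    return 1.0 - ss_res / ((o - o.mean()) ** 2).sum()


def profile_r2_over_J(
    observed_AA: PatternDistribution,
    observed_EE: PatternDistribution,
    j_grid: np.ndarray = DEFAULT_J_GRID,
) -> dict:
    """R^2(J) with the fields re-optimized at every J, plus the
    R^2 >= 0.95 interval for J (linear interpolation at the crossings)."""
    r2 = np.empty(len(j_grid))
    for i, J in enumerate(j_grid):
        _, _, ss = _best_fields(J, observed_AA, observed_EE)
        r2[i] = _joint_r2(ss, observed_AA, observed_EE)
    return {
        "J": np.asarray(j_grid, dtype=float),
        "r2": r2,
        "interval": _threshold_interval(np.asarray(j_grid, float), r2, R2_CUTOFF),
    }


def _threshold_interval(x, y, cutoff):
    """[min, max] of {x : y(x) >= cutoff} with interpolated edges."""
    above = y >= cutoff
    if not above.any():
        return (np.nan, np.nan)
    idx = np.flatnonzero(above)
    lo, hi = x[idx[0]], x[idx[-1]]
    if idx[0] > 0:
        x0, x1, y0, y1 = x[idx[0] - 1], x[idx[0]], y[idx[0] - 1], y[idx[0]]
        lo = x0 + (cutoff - y0) / (y1 - y0) * (x1 - x0)
    if idx[-1] < len(x) - 1:
        x0, x1, y0, y1 = x[idx[-1]], x[idx[-1] + 1], y[idx[-1]], y[idx[-1] + 1]
        hi = x0 + (cutoff - y0) / (y1 - y0) * (x1 - x0)
    return (float(lo), float(hi))


def _profile_field(which, best, obs_aa, obs_ee, grid):
    """R^2 profile over one field, re-optimizing J and the other field."""
    r2 = np.empty(len(grid))
    for i, b in enumerate(grid):
        def neg(theta):
            J, other = theta
            if which == "B_AA":
                return _ss_res_joint(J, b, other, (obs_aa, obs_ee))
            return _ss_res_joint(J, other, b, (obs_aa, obs_ee))

        start = [best.J, best.B_EE if which == "B_AA" else best.B_AA]
        res = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12})
        r2[i] = _joint_r2(res.fun, obs_aa, obs_ee)
    return _threshold_interval(np.asarray(grid, float), r2, R2_CUTOFF)


def fit_pure(
    observed_AA: PatternDistribution,
    observed_EE: PatternDistribution,
    j_grid: np.ndarray = DEFAULT_J_GRID,
    profile_fields: bool = True,
) -> FitResult:
    """Joint fit of (J, B_AA, B_EE) to two pure-sample pattern distributions.

    Deterministic: a coarse grid in J with exact scalar field
    optimization at each node, followed by a local Nelder-Mead polish
    of all three parameters.  Uncertainty intervals are the profile
    regions where R^2 >= 0.95.
    """
    prof = profile_r2_over_J(observed_AA, observed_EE, j_grid)
    i_best = int(np.argmax(prof["r2"]))
    J0 = prof["J"][i_best]
    b_aa0, b_ee0, _ = _best_fields(J0, observed_AA, observed_EE)

    res = optimize.minimize(
        lambda th: _ss_res_joint(th[0], th[1], th[2], (observed_AA, observed_EE)),
        [J0, b_aa0, b_ee0],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14},
    )
    J, b_aa, b_ee = res.x
    J = max(J, 0.0)
    params = IsingParameters(J=J, B_AA=b_aa, B_EE=b_ee)
    r2 = _joint_r2(res.fun, observed_AA, observed_EE)

    uncertainty = {"J": prof["interval"]}
    if profile_fields:
        for which, b_hat in (("B_AA", b_aa), ("B_EE", b_ee)):
            grid = np.round(np.arange(b_hat - 0.15, b_hat + 0.1501, 0.01), 6)
            uncertainty[which] = _profile_field(which, params, observed_AA,
                                                observed_EE, grid)
    return FitResult(params=params, r_squared=r2, uncertainty=uncertainty,
                     profile=prof)


def fit_correlation(
    observed: dict[str, CorrelationFunction],
    max_lag: int = 3,
    mean_spin: dict[str, float] | None = None,
) -> FitResult:
    """Least-squares fit of the exact ring correlation to observed C~(x).

    One shared coupling J and one field per dataset; lags
    x = 1..max_lag enter the objective (x = 0 is identically 1).

    The correlation function alone is even in B and nearly degenerate
    along a large-J / large-|B| ridge, so by itself it identifies
    neither the sign of the field nor, on noisy data, the coupling.
    Supplying each dataset's pooled mean spin via ``mean_spin`` adds
    one residual per dataset (model <S> minus observed), which pins
    the field given J and fixes its sign.  Without it the fit returns
    |B| and confines the search to J in [0, 0.5], |B| <= 1.
    """
    keys = list(observed)
    targets = {k: np.asarray(observed[k].values[1:max_lag + 1]) for k in keys}
    use_mean = mean_spin is not None

    def residuals(theta):
        J = theta[0]
        out = []
        for k, b in zip(keys, theta[1:]):
            p = IsingParameters(J=J, B_AA=b if use_mean else abs(b))
            corr, _ = closed_form_correlation(p, which="AA")
            out.append(corr.values[1:max_lag + 1] - targets[k])
            if use_mean:
                out.append(np.atleast_1d(
                    ising_mean_spin(p, p.B_AA) - mean_spin[k]))
        return np.concatenate(out)

    if all(np.abs(t).max() < 1e-12 for t in targets.values()) and not use_mean:
        params = IsingParameters(J=0.0)
        return FitResult(params=params, r_squared=1.0)

    if use_mean:
        starts = [[0.1] + [np.sign(mean_spin[k]) * 0.2 or 0.1 for k in keys],
                  [0.3] + [np.sign(mean_spin[k]) * 0.05 or 0.05 for k in keys]]
    else:
        starts = [[0.1] + [0.2] * len(keys), [0.3] + [0.05] * len(keys),
                  [0.02] + [0.5] * len(keys)]
    lower = [0.0] + [-1.0] * len(keys)
    upper = [0.5] + [1.0] * len(keys)
    best = None
    for s in starts:
        res = optimize.least_squares(residuals, s, bounds=(lower, upper),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    J = max(best.x[0], 0.0)
    fields = {k: (b if use_mean else abs(b)) for k, b in zip(keys, best.x[1:])}
    params = IsingParameters(
        J=J,
        B_AA=fields.get("AA", next(iter(fields.values()))),
        B_EE=fields.get("EE", next(iter(fields.values()))),
    )
    # R^2 reported on the correlation lags alone
    obs_vec = np.concatenate([targets[k] for k in keys])
    model_vec = []
    for k in keys:
        p = IsingParameters(J=J, B_AA=fields[k])
        corr, _ = closed_form_correlation(p, which="AA")
        model_vec.append(corr.values[1:max_lag + 1])
    model_vec = np.concatenate(model_vec)
    ss_tot = ((obs_vec - obs_vec.mean()) ** 2).sum()
    r2 = (1.0 - ((model_vec - obs_vec) ** 2).sum() / ss_tot
          if ss_tot > 1e-20 else 1.0)
    return FitResult(params=params, r_squared=r2,
                     uncertainty={}, profile={"fields": fields})


# ---------------------------------------------------------------------------
# mixed-composition model


def arrangement_distribution_matrix(
    params: IsingParameters,
    arrangements: Sequence[PhosphoArrangement] | None = None,
) -> np.ndarray:
    """Matrix P[k, l] = p_l(k): pattern distribution per arrangement."""
    arrangements = arrangements or build_arrangements()
    cols = [
        brute_force_distribution(params, labels=a).probabilities
        for a in arrangements
    ]
    return np.column_stack(cols)


def mixed_distribution(
    params: IsingParameters,
    weights: MixingWeights,
    arrangements: Sequence[PhosphoArrangement] | None = None,
) -> PatternDistribution:
    """Population pattern distribution P_k = sum_l q_l p_l(k)."""
    P = arrangement_distribution_matrix(params, arrangements)
    if len(weights.q) != P.shape[1]:
        raise ValueError("weight vector does not match arrangement count")
    return PatternDistribution(P @ weights.q, source="model")


def scenario_weights(scenario: str, ee_target: float = 0.5) -> MixingWeights:
    """Reference arrangement weights for the two extreme mixing scenarios.

    ``no_mixing``: only pure hexamers, mass ``ee_target`` on all-EE and
    the rest on all-AA.  ``fully_mixed``: independent per-monomer
    labels, q_l = m_l * ee^{n_EE} (1-ee)^{6-n_EE}.
    """
    if not 0.0 <= ee_target <= 1.0:
        raise ValueError("ee_target must lie in [0, 1]")
    arrangements = build_arrangements()
    q = np.zeros(len(arrangements))
    if scenario == "no_mixing":
        for i, a in enumerate(arrangements):
            if a.ee_count == 0:
                q[i] = 1.0 - ee_target
            elif a.ee_count == 6:
                q[i] = ee_target
    elif scenario == "fully_mixed":
        for i, a in enumerate(arrangements):
            q[i] = (a.multiplicity * ee_target**a.ee_count
                    * (1.0 - ee_target) ** (6 - a.ee_count))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return MixingWeights(q=q, scenario=scenario)


def fit_mixing_weights(
    observed: PatternDistribution,
    params: IsingParameters,
    lambda_weight: float = 0.1,
    ee_target: float = 0.5,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[MixingWeights, FitResult]:
    """Fit the arrangement weights q_l on the simplex.

    Minimizes sum_k (P_k(q) - P_k^obs)^2 + lambda * (f_EE(q) - ee_target)^2
    subject to sum q_l = 1, 0 <= q_l <= 1, with (J, B_AA, B_EE) held
    fixed at the pure-sample estimates.  The objective is a convex
    quadratic over the simplex; SLSQP from a fixed multi-start list
    (seeded Dirichlet draws plus the two extreme scenarios) makes the
    result deterministic.  Note q itself is not identifiable (14
    weights, 13 probabilities); the contract is on the fitted P_k and
    on f_EE.
    """
    arrangements = build_arrangements()
    P = arrangement_distribution_matrix(params, arrangements)
    ee = np.array([a.ee_count for a in arrangements]) / 6.0
    obs = observed.probabilities

    def objective(q):
        resid = P @ q - obs
        return (resid**2).sum() + lambda_weight * (ee @ q - ee_target) ** 2

    def grad(q):
        return 2.0 * P.T @ (P @ q - obs) + 2.0 * lambda_weight * (ee @ q - ee_target) * ee

    rng = np.random.default_rng(seed)
    starts = [
        scenario_weights("fully_mixed", ee_target).q,
        scenario_weights("no_mixing", ee_target).q,
        np.full(len(arrangements), 1.0 / len(arrangements)),
    ]
    starts += [rng.dirichlet(np.ones(len(arrangements)))
               for _ in range(max(0, n_starts - len(starts)))]

    constraints = [{"type": "eq", "fun": lambda q: q.sum() - 1.0,
                    "jac": lambda q: np.ones_like(q)}]
    bounds = [(0.0, 1.0)] * len(arrangements)
    best = None
    for q0 in starts:
        res = optimize.minimize(objective, q0, jac=grad, method="SLSQP",
                                bounds=bounds, constraints=constraints,
                                options={"maxiter": 500, "ftol": 1e-14})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("q_l optimization failed to converge from all starts")

    q = np.clip(best.x, 0.0, 1.0)
    q /= q.sum()
    weights = MixingWeights(q=q, lambda_weight=lambda_weight, scenario="free")
    model = PatternDistribution(P @ q, source="model")
    return weights, FitResult(
        params=params,
        r_squared=r_squared(model, observed),
        profile={"model": model, "f_EE": float(ee @ q)},
    )


def fit_delta_J(
    observed: PatternDistribution,
    params: IsingParameters,
    ee_target: float = 0.5,
    bounds: tuple[float, float] = (-0.5, 0.5),
) -> tuple[float, FitResult]:
    """One-dimensional fit of the cross-coupling offset delta_J.

    Unlike neighbours couple with J - delta_J (delta_J > 0 weakens the
    AA-EE interaction).  Arrangement weights are held at the
    fully-mixed reference; (J, B_AA, B_EE) stay fixed.
    """
    weights = scenario_weights("fully_mixed", ee_target)

    def neg_fit(dj):
        p = IsingParameters(J=params.J, B_AA=params.B_AA, B_EE=params.B_EE,
                            delta_J=dj)
        model = mixed_distribution(p, weights)
        return ((model.probabilities - observed.probabilities) ** 2).sum()

    res = optimize.minimize_scalar(neg_fit, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-7})
    dj = float(res.x)
    fitted = IsingParameters(J=params.J, B_AA=params.B_AA, B_EE=params.B_EE,
                             delta_J=dj)
    model = mixed_distribution(fitted, weights)
    return dj, FitResult(params=fitted, r_squared=r_squared(model, observed))


def enrichment(q_fitted: MixingWeights, q_reference: MixingWeights) -> np.ndarray:
    """Enrichment factor alpha_l = q_l(fitted) / q_l(reference).

    Values above 1 mark arrangements over-represented relative to the
    reference (normally the fully-mixed scenario); alpha is identically
    1 when the two weight vectors coincide.
    """
    ref = q_reference.q
    if np.any(ref <= 0.0):
        raise ValueError("reference weights must be strictly positive")
    return q_fitted.q / ref
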