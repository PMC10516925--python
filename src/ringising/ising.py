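"""Nearest-neighbour Ising model on the six-site ring.

Each subunit carries a spin S_i = +1 (A-loop exposed) or -1 (buried).
The energy of a ring, in units of the effective thermal energy
(beta = 1 throughout), is

    H(S) = - sum_<ij> J_ij S_i S_j - sum_i B(sigma_i) S_i

with the six nearest-neighbour pairs counted once each.  For a pure
sample every subunit shares one local field (B_AA or B_EE) and
J_ij = J.  For mixed hexamers the phosphorylation label sigma_i in
{0 (AA), 1 (EE)} selects the field per site, and the cross coupling
between unlike neighbours may be weakened: J_ij = J - delta_J when
sigma_i != sigma_j.

Equilibrium pattern probabilities are Boltzmann weights aggregated
over symmetry classes: p(k) = Omega_k exp(-H_k) / Z for uniform
labels, and a Boltzmann sum over class members when the labelling
breaks the ring symmetry.  The module also provides the independent-
subunit binomial null, empirical and exact correlation functions, the
2x2 transfer-matrix spectrum and correlation length, and the
field-response (Hill) analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .rings import (
    DIHEDRAL_GROUP,
    N_SITES,
    ConformationalPattern,
    PhosphoArrangement,
    build_patterns,
    enumerate_configurations,
)

STATE_TO_SPIN = {"E": 1.0, "B": -1.0, "U": np.nan}

#: number of distinct ring separations reported for empirical correlations
#: (x and 6-x coincide on the ring, so lags 0..3 carry all information)
MAX_EMPIRICAL_LAG = 3


@dataclass(frozen=True)
class IsingParameters:
    """Dimensionless model parameters (energies in units of k_B T).

    beta is fixed at 1: the effective thermal energy is the energy
    unit, so J and the fields are directly comparable to free-energy
    differences.
    """

    J: float
    B_AA: float = 0.0
    B_EE: float = 0.0
    delta_J: float = 0.0

    beta: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self):
        for name in ("J", "B_AA", "B_EE", "delta_J"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def local_field(self, sigma: int) -> float:
        return self.B_EE if sigma else self.B_AA


@dataclass
class PatternDistribution:
    """Probability vector over the 13 conformational patterns."""

    probabilities: np.ndarray
    source: str = "model"
    n_rings: int | None = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < -1e-15):
            raise ValueError("pattern probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("pattern probabilities must sum to 1")


@dataclass
class CorrelationFunction:
    """Normalized pair correlation C~(x) = C(x)/C(0) by ring separation."""

    lags: np.ndarray
    values: np.ndarray
    raw_c0: float
    n_pairs: np.ndarray | None = None


@dataclass
class TransferSpectrum:
    """Eigenvalues of the 2x2 transfer matrix and the correlation length.

    xi satisfies 1/xi = ln(lambda_plus/lambda_minus); when
    lambda_minus <= 0 (J <= 0) the correlation length is reported as 0.
    """

    lambda_plus: float
    lambda_minus: float
    xi: float


@dataclass
class StateCallDataset:
    """Per-hexamer ordered state calls: an (n, 6) array over {E, B, U}."""

    rows: np.ndarray
    label: str = ""

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype="U1")
        if rows.ndim != 2 or rows.shape[1] != N_SITES:
            raise ValueError(f"rows must be an (n, {N_SITES}) array")
        bad = ~np.isin(rows, ["E", "B", "U"])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid state symbol {rows[i, j]!r} at row {i}, site {j}"
            )
        self.rows = rows

    def __len__(self) -> int:
        return self.rows.shape[0]

    def spins(self) -> np.ndarray:
        """Float spin matrix with NaN for undefined calls."""
        out = np.full(self.rows.shape, np.nan)
        out[self.rows == "E"] = 1.0
        out[self.rows == "B"] = -1.0
        return out


def _resolve_sigma(labels) -> np.ndarray:
    """Normalize a labelling argument to a 6-vector of 0/1."""
    if isinstance(labels, str):
        if labels == "AA":
            return np.zeros(N_SITES, dtype=int)
        if labels == "EE":
            return np.ones(N_SITES, dtype=int)
        raise ValueError(f"unknown uniform label {labels!r}; expected 'AA' or 'EE'")
    if isinstance(labels, PhosphoArrangement):
        return np.asarray(labels.sigma, dtype=int)
    sigma = np.asarray(labels, dtype=int)
    if sigma.shape != (N_SITES,):
        raise ValueError(f"arrangement must have length {N_SITES}")
    if not np.isin(sigma, [0, 1]).all():
        raise ValueError("arrangement entries must be 0 (AA) or 1 (EE)")
    return sigma


def hamiltonian(config: Sequence[int], params: IsingParameters, labels="AA") -> float:
    """Ring energy of one configuration, in k_B T units."""
    s = np.asarray(config, dtype=float)
    if s.shape != (N_SITES,):
        raise ValueError(f"configuration must have length {N_SITES}")
    sigma = _resolve_sigma(labels)
    s_next = np.roll(s, -1)
    sigma_next = np.roll(sigma, -1)
    couplings = np.where(sigma == sigma_next, params.J, params.J - params.delta_J)
    fields = np.where(sigma == 1, params.B_EE, params.B_AA)
    return float(-(couplings * s * s_next).sum() - (fields * s).sum())


@lru_cache(maxsize=8)
def _config_arrays(group=DIHEDRAL_GROUP):
    """Cached per-configuration and per-pattern lookup arrays.

    Returns (spins[64,6], pattern_index[64], omega[K], n_exposed[K],
    neighbor_sum[K], magnetization[K]) for the given symmetry group.
    """
    configs = enumerate_configurations()
    patterns = build_patterns(group)
    lookup = {c: p.pattern_id - 1 for p in patterns for c in p.members}
    spins = np.array(configs, dtype=float)
    pattern_index = np.array([lookup[c] for c in configs])
    omega = np.array([p.omega for p in patterns], dtype=float)
    n_exposed = np.array([p.n_exposed for p in patterns], dtype=float)
    reps = np.array([p.canonical_form for p in patterns], dtype=float)
    neighbor_sum = (reps * np.roll(reps, -1, axis=1)).sum(axis=1)
    magnetization = reps.sum(axis=1)
    return spins, pattern_index, omega, n_exposed, neighbor_sum, magnetization


def pattern_distribution(
    params: IsingParameters,
    patterns: Sequence[ConformationalPattern] | None = None,
    labels: str = "AA",
) -> PatternDistribution:
    """Boltzmann distribution over patterns for a uniform labelling.

    All members of a pattern class share one energy when the labels
    are uniform, so p(k) is proportional to Omega_k exp(-H_k);
    evaluated in log space for stability.
    """
    if labels not in ("AA", "EE"):
        raise ValueError("pattern_distribution requires a uniform label; "
                         "use brute_force_distribution for mixed arrangements")
    _, _, omega, _, neighbor_sum, magnetization = _config_arrays()
    B = params.B_EE if labels == "EE" else params.B_AA
    logw = np.log(omega) + params.J * neighbor_sum + B * magnetization
    probs = np.exp(logw - logsumexp(logw))
    return PatternDistribution(probs / probs.sum(), source="model")


def brute_force_distribution(
    params: IsingParameters,
    patterns: Sequence[ConformationalPattern] | None = None,
    labels="AA",
) -> PatternDistribution:
    """Pattern distribution by direct summation over all 64 configurations.

    For uniform labels this is an independent check on
    :func:`pattern_distribution`.  For a concrete phosphorylation
    arrangement it is the primary evaluator of the per-arrangement
    distribution p_l(k): members of a pattern class can differ in
    energy once the labels break ring symmetry, so the class weight is
    the Boltzmann sum over its members (equivalently, all relative
    orientations of pattern and arrangement are summed over).
    """
    spins, pattern_index, _, _, _, _ = _config_arrays()
    sigma = _resolve_sigma(labels)
    sigma_next = np.roll(sigma, -1)
    couplings = np.where(sigma == sigma_next, params.J, params.J - params.delta_J)
    fields = np.where(sigma == 1, params.B_EE, params.B_AA)
    neg_H = (spins * np.roll(spins, -1, axis=1)) @ couplings + spins @ fields
    n_patterns = pattern_index.max() + 1
    log_class = np.array(
        [logsumexp(neg_H[pattern_index == k]) for k in range(n_patterns)]
    )
    probs = np.exp(log_class - logsumexp(log_class))
    return PatternDistribution(probs / probs.sum(), source="model")


def binomial_null(p: float, patterns: Sequence[ConformationalPattern] | None = None
                  ) -> PatternDistribution:
    """Independent-subunit null: P_k = Omega_k p^{n_k} (1-p)^{6-n_k}."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    _, _, omega, n_exposed, _, _ = _config_arrays()
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = omega * p**n_exposed * (1.0 - p) ** (N_SITES - n_exposed)
    return PatternDistribution(probs / probs.sum(), source="model")


def empirical_correlation(data: StateCallDataset) -> CorrelationFunction:
    """Pair correlation estimated from state calls with Un exclusion.

    C(x) = <S_{n,i} S_{n,i+x}>_{n,i} - <S>^2.  The mean <S> pools all
    defined (non-Un) monomers; each pair average runs over every
    hexamer and every site pair (i, i+x mod 6) in which both members
    are defined.  Returns C~(x) = C(x)/C(0) for x = 0..3.
    """
    spins = data.spins()
    if spins.shape[0] < 1:
        raise ValueError("dataset must contain at least one ring")
    mean_s = np.nanmean(spins)
    values = np.empty(MAX_EMPIRICAL_LAG + 1)
    n_pairs = np.empty(MAX_EMPIRICAL_LAG + 1, dtype=int)
    for x in range(MAX_EMPIRICAL_LAG + 1):
        prod = spins * np.roll(spins, -x, axis=1)
        n_pairs[x] = np.isfinite(prod).sum()
        values[x] = np.nanmean(prod) - mean_s**2
    c0 = values[0]
    if c0 <= 0.0:
        raise ValueError(
            "degenerate dataset: zero conformational variance (C(0) = 0)"
        )
    return CorrelationFunction(
        lags=np.arange(MAX_EMPIRICAL_LAG + 1),
        values=values / c0,
        raw_c0=float(c0),
        n_pairs=n_pairs,
    )


def transfer_spectrum(J: float, B: float) -> TransferSpectrum:
    """Eigenvalues of the 2x2 transfer matrix and correlation length.

    lambda_+- = e^J cosh B +- sqrt(e^{2J} sinh^2 B + e^{-2J});
    1/xi = ln(lambda_+/lambda_-).  lambda_- is positive iff J > 0; at
    J <= 0 the correlation length is reported as 0 (for J < 0 the
    correlation alternates in sign and a decay length in this sense
    does not exist).
    """
    root = math.sqrt(math.exp(2 * J) * math.sinh(B) ** 2 + math.exp(-2 * J))
    lam_p = math.exp(J) * math.cosh(B) + root
    lam_m = math.exp(J) * math.cosh(B) - root
    if lam_m <= 1e-12 * lam_p:  # J <= 0 up to rounding: no decay length
        lam_m = max(lam_m, 0.0)
        xi = 0.0
    else:
        xi = 1.0 / math.log(lam_p / lam_m)
    return TransferSpectrum(lambda_plus=lam_p, lambda_minus=lam_m, xi=xi)


def _transfer_matrix(J: float, B: float) -> np.ndarray:
    # symmetric splitting of the field term; basis order (+1, -1)
    return np.array(
        [
            [math.exp(J + B), math.exp(-J)],
            [math.exp(-J), math.exp(J - B)],
        ]
    )


def closed_form_correlation(
    params: IsingParameters, which: str = "AA", n_sites: int = N_SITES
) -> tuple[CorrelationFunction, TransferSpectrum]:
    """Exact correlation function of the finite ring via the transfer matrix.

    Evaluates C(x) = Tr(Sz T^x Sz T^{N-x})/Tr(T^N) - <S>^2 in the
    transfer-matrix eigenbasis, which is exact for the periodic chain
    at any field (for B != 0 it contains a small x-independent term on
    top of the familiar two-exponential decay; see
    :func:`two_exponential_correlation`).  Returns C~(x) for
    x = 0..n_sites together with the spectrum (lambda_+, lambda_-, xi).
    """
    B = params.B_EE if which == "EE" else params.B_AA
    spectrum = transfer_spectrum(params.J, B)
    T = _transfer_matrix(params.J, B)
    lam, V = np.linalg.eigh(T)  # ascending: lam[1] = lambda_plus
    S = V.T @ np.diag([1.0, -1.0]) @ V  # spin operator in eigenbasis
    N = n_sites
    Z = (lam**N).sum()
    mean_s = (lam**N * np.diag(S)).sum() / Z
    x = np.arange(N + 1)
    lam_x = lam[:, None] ** x  # (2, N+1)
    lam_nx = lam[:, None] ** (N - x)
    # C(x) = sum_{a,b} lam_a^{N-x} lam_b^x S_ab S_ba / Z - <S>^2
    pair = np.einsum("ax,bx,ab,ba->x", lam_nx, lam_x, S, S)
    C = pair / Z - mean_s**2
    c0 = C[0]
    if c0 <= 0.0:
        raise ValueError("degenerate parameters: zero spin variance")
    corr = CorrelationFunction(lags=x, values=C / c0, raw_c0=float(c0))
    return corr, spectrum


def two_exponential_correlation(xi: float, n_sites: int = N_SITES) -> np.ndarray:
    """Two-exponential ring decay C~(x) = [e^{-x/xi} + e^{-(N-x)/xi}] / [1 + e^{-N/xi}].

    Exact at zero field; for B != 0 it approximates the finite-ring
    correlation to within ~1e-4 in the parameter range of interest.
    """
    x = np.arange(n_sites + 1, dtype=float)
    if xi <= 0.0:
        out = np.zeros(n_sites + 1)
        out[0] = out[n_sites] = 1.0
        return out
    return (np.exp(-x / xi) + np.exp(-(n_sites - x) / xi)) / (1.0 + np.exp(-n_sites / xi))


def mean_spin(params: IsingParameters, B: float) -> float:
    """Exact <S> at field B by enumeration over the 64 configurations."""
    spins, _, _, _, _, _ = _config_arrays()
    neg_H = params.J * (spins * np.roll(spins, -1, axis=1)).sum(1) + B * spins.sum(1)
    w = np.exp(neg_H - logsumexp(neg_H))
    return float((w[:, None] * spins).sum() / N_SITES)


def response_curve(J: float, B_grid: np.ndarray) -> tuple[np.ndarray, float]:
    """Exposed fraction f_Ex(B) and the effective Hill coefficient.

    f_Ex(B) = (1 + <S>(B))/2 from exact enumeration.  The Hill
    coefficient is defined as the midpoint-slope ratio

        n_H = (df/dB at f = 1/2) / (df/dB at f = 1/2, J = 0),

    so n_H(J=0) = 1 by construction.  At B = 0 (the midpoint, by spin-
    flip symmetry) the slope equals Var(M)/12 with M the total spin,
    giving n_H = Var_J(M)/6 in closed form from enumeration.
    """
    B_grid = np.asarray(B_grid, dtype=float)
    params = IsingParameters(J=J)
    f = np.array([(1.0 + mean_spin(params, b)) / 2.0 for b in B_grid])
    spins, _, _, _, _, _ = _config_arrays()
    neg_H = J * (spins * np.roll(spins, -1, axis=1)).sum(1)
    w = np.exp(neg_H - logsumexp(neg_H))
    M = spins.sum(1)
    var_M = float((w * M**2).sum() - (w * M).sum() ** 2)
    return f, var_M / N_SITES
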