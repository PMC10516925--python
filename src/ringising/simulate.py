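"""Synthetic hexamer ensembles and density volumes.

Samples rings exactly from the Boltzmann distribution of the ring
Ising model (the 64-state space is enumerated, so no MCMC and no
convergence questions), applies independent undefined-state (Un)
masking at a stated per-monomer rate, and tabulates pattern counts —
the statistical structure the downstream estimators assume.  Presets
mirror the cryo-EM study conditions: dataset sizes of order 1e4-1e5
rings and Un rates of 25.7% (AA), 18.2% (EE); the mixed-sample rate
(30.4%) is implied by its printed ring counts.

Randomness contract: one integer seed per dataset, split into
independent child streams (arrangement draw, configuration draw, Un
mask) via ``numpy.random.SeedSequence.spawn``, so each stage is
reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ising import IsingParameters, PatternDistribution, StateCallDataset
from .fitting import MixingWeights, scenario_weights
from .rings import N_SITES, build_arrangements, build_patterns, enumerate_configurations
from .volumes import DensityVolume


@dataclass
class SimulationSpec:
    """Conditions for one simulated dataset.

    composition is ``"AA"``/``"EE"`` for a pure sample or a
    :class:`MixingWeights` over the 14 arrangements; un_rate is the
    per-monomer probability of an undefined call.
    """

    params: IsingParameters
    composition: str | MixingWeights = "AA"
    n_rings: int = 10_000
    un_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.un_rate < 1.0:
            raise ValueError("un_rate must lie in [0, 1)")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")


#: study-scale presets: particle counts and Un rates of the three datasets
PAPER_PARAMS = IsingParameters(J=0.14, B_AA=0.19, B_EE=-0.25)

PRESETS: dict[str, SimulationSpec] = {
    "AA": SimulationSpec(params=PAPER_PARAMS, composition="AA",
                         n_rings=140_475, un_rate=0.257),
    "EE": SimulationSpec(params=PAPER_PARAMS, composition="EE",
                         n_rings=371_557, un_rate=0.182),
    "mixed": SimulationSpec(params=PAPER_PARAMS,
                            composition=scenario_weights("fully_mixed", 0.5),
                            n_rings=175_284, un_rate=0.304),
}


def preset(name: str, seed: int = 0) -> SimulationSpec:
    """A named study-scale preset with the seed substituted."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}") from None
    return replace(spec, seed=seed)


def expected_defined_count(n_rings: int, un_rate: float) -> float:
    """Expected number of fully defined rings, n * (1 - u)^6."""
    return n_rings * (1.0 - un_rate) ** N_SITES


def _config_probabilities(params: IsingParameters, sigma) -> np.ndarray:
    """Boltzmann probabilities of the 64 configurations for one labelling."""
    configs = np.array(enumerate_configurations(), dtype=float)
    sigma = np.asarray(sigma, dtype=int)
    sigma_next = np.roll(sigma, -1)
    couplings = np.where(sigma == sigma_next, params.J, params.J - params.delta_J)
    fields = np.where(sigma == 1, params.B_EE, params.B_AA)
    neg_H = (configs * np.roll(configs, -1, axis=1)) @ couplings + configs @ fields
    w = np.exp(neg_H - neg_H.max())
    return w / w.sum()


def sample_hexamers(spec: SimulationSpec) -> StateCallDataset:
    """Exact Boltzmann sample of ring conformations (no Un masking).

    Each ring draws an arrangement l ~ q (pure compositions are a
    point mass), then one of the 64 configurations by inverse CDF over
    the enumerated Boltzmann table for that arrangement.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_arr, rng_cfg, _ = [np.random.default_rng(s) for s in ss.spawn(3)]
    configs = np.array(enumerate_configurations())
    chosen = np.empty(spec.n_rings, dtype=np.int64)

    if isinstance(spec.composition, str):
        sigma = np.zeros(N_SITES, int) if spec.composition == "AA" else np.ones(N_SITES, int)
        if spec.composition not in ("AA", "EE"):
            raise ValueError(f"unknown composition {spec.composition!r}")
        probs = _config_probabilities(spec.params, sigma)
        chosen[:] = rng_cfg.choice(64, size=spec.n_rings, p=probs)
        label = spec.composition
    else:
        arrangements = build_arrangements()
        arr_idx = rng_arr.choice(len(arrangements), size=spec.n_rings,
                                 p=spec.composition.q)
        for i, a in enumerate(arrangements):
            sel = arr_idx == i
            n = int(sel.sum())
            if n == 0:
                continue
            probs = _config_probabilities(spec.params, a.sigma)
            chosen[sel] = rng_cfg.choice(64, size=n, p=probs)
        label = "mixed"

    rows = np.where(configs[chosen] == 1, "E", "B")
    return StateCallDataset(rows=rows, label=label)


def apply_un_mask(
    data: StateCallDataset,
    un_rate: float,
    seed: int,
    site_correlation: float = 0.0,
) -> StateCallDataset:
    """Replace monomer calls by Un, independently at rate ``un_rate``.

    ``site_correlation`` (intraclass correlation in [0, 1)) optionally
    makes Un calls cluster within rings via a per-ring beta-distributed
    rate with mean ``un_rate`` — a sensitivity knob for the assumption
    that undefined calls occur independently across sites; default off.
    """
    if not 0.0 <= un_rate < 1.0:
        raise ValueError("un_rate must lie in [0, 1)")
    if un_rate == 0.0:
        return StateCallDataset(rows=data.rows.copy(), label=data.label)
    rng = np.random.default_rng(seed)
    n = len(data)
    if site_correlation > 0.0:
        # beta-binomial thinning: ICC rho => concentration (1-rho)/rho
        c = (1.0 - site_correlation) / site_correlation
        rates = rng.beta(un_rate * c, (1.0 - un_rate) * c, size=(n, 1))
    else:
        rates = un_rate
    mask = rng.random((n, N_SITES)) < rates
    rows = data.rows.copy()
    rows[mask] = "U"
    return StateCallDataset(rows=rows, label=data.label)


def simulate_dataset(spec: SimulationSpec) -> StateCallDataset:
    """Sample rings and apply the spec's Un masking in one call."""
    data = sample_hexamers(spec)
    ss = np.random.SeedSequence(spec.seed)
    un_seed = ss.spawn(3)[2]
    return apply_un_mask(data, spec.un_rate, seed=un_seed) if spec.un_rate else data


def tabulate_patterns(data: StateCallDataset) -> tuple[PatternDistribution, np.ndarray]:
    """Pattern counts over the fully defined rings.

    Rings containing any Un call are dropped; the rest map to their
    dihedral pattern class.  Returns (frequencies, counts).
    """
    patterns = build_patterns()
    defined = ~(data.rows == "U").any(axis=1)
    rows = data.rows[defined]
    if rows.shape[0] == 0:
        raise ValueError("no fully defined rings to tabulate")
    codes = ((rows == "E").astype(np.int64)
             @ (1 << np.arange(N_SITES - 1, -1, -1)))
    # configuration index -> pattern index lookup
    lookup = np.empty(64, dtype=np.int64)
    for p in patterns:
        for c in p.members:
            idx = int("".join("1" if s == 1 else "0" for s in c), 2)
            lookup[idx] = p.pattern_id - 1
    counts = np.bincount(lookup[codes], minlength=len(patterns))
    dist = PatternDistribution(counts / counts.sum(), source="observed",
                               n_rings=int(counts.sum()))
    return dist, counts


# ---------------------------------------------------------------------------
# synthetic per-subunit density volumes


_BLOB_CENTER = (8, 8, 8)
_BLOB_WIDTH = 2.0
_DEFAULT_SHAPE = (16, 16, 16)


def reference_blob_volume(shape=_DEFAULT_SHAPE, signal_level: float = 1.0) -> DensityVolume:
    """Noise-free Gaussian blob in the A-loop region, for mask building."""
    zz, yy, xx = np.indices(shape)
    r2 = sum((g - c) ** 2 for g, c in zip((zz, yy, xx), _BLOB_CENTER))
    grid = signal_level * np.exp(-r2 / (2.0 * _BLOB_WIDTH**2))
    return DensityVolume(grid=grid)


def make_synthetic_volumes(
    n: int,
    class_fractions=(0.5, 0.3, 0.2),
    signal_level: float = 1.0,
    noise_sd: float = 0.0,
    shape=_DEFAULT_SHAPE,
    seed: int = 0,
) -> tuple[list[DensityVolume], list[str]]:
    """Synthetic per-subunit volumes with ground-truth labels.

    Buried subunits get a full-strength Gaussian blob inside the fixed
    A-loop region, exposed subunits no blob, undefined subunits an
    attenuated (half-strength) blob, all plus i.i.d. Gaussian noise.
    ``class_fractions`` orders as (Bu, Ex, Un).  Returns (volumes,
    labels).
    """
    fractions = np.asarray(class_fractions, dtype=float)
    if fractions.min() < 0 or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("class_fractions must lie on the simplex")
    rng = np.random.default_rng(seed)
    labels = rng.choice(["Bu", "Ex", "Un"], size=n, p=fractions)
    base = reference_blob_volume(shape, signal_level).grid
    scale = {"Bu": 1.0, "Ex": 0.0, "Un": 0.5}
    volumes = []
    for lab in labels:
        grid = scale[lab] * base
        if noise_sd > 0.0:
            grid = grid + rng.normal(0.0, noise_sd, size=shape)
        volumes.append(DensityVolume(grid=grid))
    return volumes, list(labels)
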