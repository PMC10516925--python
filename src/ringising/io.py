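"""File formats, run configuration, and the pipeline driver.

All tabular artefacts are tab-separated text with a mandatory header
row and ``#`` comment lines, chosen for diff-ability: state-call
tables (one hexamer per row, six columns over E/B/U), pattern-count
tables keyed by pattern_id, and fit reports.  Machine-readable
numbers are written with 12 significant digits so downstream equality
checks are meaningful.

A :class:`RunConfig` (flat key-value, YAML on disk) drives
:func:`run_pipeline`, which executes the requested stages in
dependency order — simulate, correlate, fit-pure, fit-mixed — and
writes a run log carrying the package version, seeds, the config
hash, and a hash of the enumerated pattern table so numbering
mismatches across versions are detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ising import IsingParameters, PatternDistribution, StateCallDataset, empirical_correlation
from .fitting import fit_mixing_weights, fit_pure, scenario_weights, enrichment
from .rings import (
    arrangements_to_frame,
    build_arrangements,
    build_patterns,
    patterns_to_frame,
)
from .simulate import PRESETS, SimulationSpec, preset, simulate_dataset, tabulate_patterns

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# state-call tables


def write_state_calls(path: str | Path, data: StateCallDataset) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label={data.label}\n")
        fh.write("\t".join(f"s{i+1}" for i in range(6)) + "\n")
        for row in data.rows:
            fh.write("\t".join(row) + "\n")


def read_state_calls(path: str | Path) -> StateCallDataset:
    """Parse a state-call table, reporting the line number on bad input."""
    label = ""
    rows: list[list[str]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "label=" in line:
                    label = line.split("label=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                continue
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 state columns, got {len(fields)}"
                )
            for sym in fields:
                if sym not in ("E", "B", "U"):
                    raise ValueError(
                        f"{path}:{lineno}: invalid state symbol {sym!r} "
                        "(expected E, B, or U)"
                    )
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return StateCallDataset(rows=np.array(rows, dtype="U1"), label=label)


# ---------------------------------------------------------------------------
# pattern-count tables


def write_pattern_counts(path: str | Path, counts: np.ndarray,
                         label: str = "") -> None:
    patterns = build_patterns()
    if len(counts) != len(patterns):
        raise ValueError("counts length does not match the pattern set")
    with open(path, "w") as fh:
        fh.write(f"# label={label}\n")
        fh.write("pattern_id\tcanonical_form\tomega\tn_exposed\tcount\n")
        for p, c in zip(patterns, counts):
            fh.write(f"{p.pattern_id}\t{p.label}\t{p.omega}\t{p.n_exposed}\t{int(c)}\n")


def read_pattern_counts(path: str | Path) -> PatternDistribution:
    """Read a 13-row count table back into an observed distribution."""
    patterns = build_patterns()
    df = pd.read_csv(path, sep="\t", comment="#")
    if "pattern_id" not in df.columns or "count" not in df.columns:
        raise ValueError(f"{path}: expected columns pattern_id and count")
    counts = np.zeros(len(patterns))
    seen = set()
    for _, row in df.iterrows():
        k = int(row["pattern_id"])
        if not 1 <= k <= len(patterns):
            raise ValueError(f"{path}: unknown pattern_id {k}")
        if row["count"] < 0:
            raise ValueError(f"{path}: negative count for pattern {k}")
        counts[k - 1] = row["count"]
        seen.add(k)
    missing = set(range(1, len(patterns) + 1)) - seen
    if missing:
        raise ValueError(f"{path}: missing pattern_id(s) {sorted(missing)}")
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{path}: all counts are zero")
    return PatternDistribution(counts / total, source="observed",
                               n_rings=int(total))


def write_distribution(path: str | Path, dist: PatternDistribution,
                       label: str = "") -> None:
    patterns = build_patterns()
    with open(path, "w") as fh:
        fh.write(f"# label={label}\tsource={dist.source}\n")
        fh.write("pattern_id\tprobability\n")
        for p, v in zip(patterns, dist.probabilities):
            fh.write(f"{p.pattern_id}\t{_FLOAT_FMT % v}\n")


def write_pattern_table(path: str | Path) -> None:
    patterns_to_frame(build_patterns()).to_csv(path, sep="\t", index=False)


def write_arrangement_table(path: str | Path) -> None:
    arrangements_to_frame(build_arrangements()).to_csv(path, sep="\t", index=False)


def write_fit_report(path: str | Path, result) -> None:
    """Key-value fit report plus a machine-readable interval table."""
    with open(path, "w") as fh:
        fh.write(f"# ringising {__version__} fit report\n")
        fh.write("parameter\testimate\tlower\tupper\n")
        p = result.params
        for name, value in (("J", p.J), ("B_AA", p.B_AA), ("B_EE", p.B_EE)):
            lo, hi = result.uncertainty.get(name, (float("nan"), float("nan")))
            fh.write(f"{name}\t{_FLOAT_FMT % value}\t{_FLOAT_FMT % lo}\t{_FLOAT_FMT % hi}\n")
        fh.write(f"R2\t{_FLOAT_FMT % result.r_squared}\t\t\n")


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run; round-trips via YAML."""

    stages: list[str] = dc_field(default_factory=list)
    out_dir: str = "."
    seed: int = 0
    preset_aa: str = "AA"
    preset_ee: str = "EE"
    preset_mixed: str = "mixed"
    lambda_weight: float = 0.1
    ee_target: float = 0.5
    scale: float = 1.0  # multiplies preset ring counts (downscaling for tests)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True).encode()
        ).hexdigest()[:16]


def _scaled_preset(name: str, seed: int, scale: float) -> SimulationSpec:
    spec = preset(name, seed=seed)
    if scale != 1.0:
        from dataclasses import replace

        spec = replace(spec, n_rings=max(1, int(spec.n_rings * scale)))
    return spec


def pattern_table_hash() -> str:
    """Stable hash of the enumerated pattern table (detects renumbering)."""
    frame = patterns_to_frame(build_patterns())
    return hashlib.sha256(
        frame.to_csv(index=False).encode()
    ).hexdigest()[:16]


_KNOWN_STAGES = ("enumerate", "simulate", "correlate", "fit-pure", "fit-mixed")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a report dict; all tables and a run log land in
    ``config.out_dir``.  Identical configs (same seeds) produce
    byte-identical tabular outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "pattern_table_hash": pattern_table_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
    }
    unknown = [s for s in config.stages if s not in _KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; expected {_KNOWN_STAGES}")
    if not config.stages:
        report["warning"] = "empty stage list: nothing to do"
        return report

    datasets: dict[str, StateCallDataset] = {}
    dists: dict[str, PatternDistribution] = {}

    if "enumerate" in config.stages:
        write_pattern_table(out / "patterns.tsv")
        write_arrangement_table(out / "arrangements.tsv")

    needs_data = {"simulate", "correlate", "fit-pure", "fit-mixed"} & set(config.stages)
    if needs_data:
        for name, key in (("AA", config.preset_aa), ("EE", config.preset_ee),
                          ("mixed", config.preset_mixed)):
            spec = _scaled_preset(key, config.seed, config.scale)
            datasets[name] = simulate_dataset(spec)
            dist, counts = tabulate_patterns(datasets[name])
            dists[name] = dist
            write_pattern_counts(out / f"counts_{name}.tsv", counts, label=name)

    if "correlate" in config.stages:
        corr_rows = []
        for name, data in datasets.items():
            corr = empirical_correlation(data)
            for x, v in zip(corr.lags, corr.values):
                corr_rows.append({"dataset": name, "lag": int(x),
                                  "C_normalized": v})
        pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)
        report["correlations"] = str(out / "correlations.tsv")

    if "fit-pure" in config.stages:
        fit = fit_pure(dists["AA"], dists["EE"])
        write_fit_report(out / "fit_pure.tsv", fit)
        report["fit_pure"] = {
            "J": fit.params.J, "B_AA": fit.params.B_AA,
            "B_EE": fit.params.B_EE, "R2": fit.r_squared,
        }

    if "fit-mixed" in config.stages:
        base = report.get("fit_pure")
        params = (IsingParameters(J=base["J"], B_AA=base["B_AA"], B_EE=base["B_EE"])
                  if base else PRESETS["AA"].params)
        weights, fit = fit_mixing_weights(
            dists["mixed"], params,
            lambda_weight=config.lambda_weight, ee_target=config.ee_target,
        )
        ref = scenario_weights("fully_mixed", config.ee_target)
        alpha = enrichment(weights, ref)
        pd.DataFrame({
            "arrangement_id": [a.arrangement_id for a in build_arrangements()],
            "q": weights.q, "q_fully_mixed": ref.q, "alpha": alpha,
        }).to_csv(out / "mixing_weights.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
        report["fit_mixed"] = {"R2": fit.r_squared,
                               "f_EE": weights.ee_fraction}

    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
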