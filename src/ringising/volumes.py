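"""Mask-overlap classification of per-subunit density volumes.

A reference mask marking the buried A-loop density is built by
averaging reference volumes, thresholding, and dilating the white
region by one voxel (mask1) or two (mask2).  Each subunit volume n is
scored by its overlap intensities

    I_1,n = sum_i D_{i,n} M_{1,i},    I_2,n = sum_i D_{i,n} M_{2,i},

where D is the density grid and M the binary mask.  Large overlap on
both masks calls the subunit buried (Bu), small overlap on both calls
it exposed (Ex), and intermediate volumes are left undefined (Un)
rather than forced into either class.  The Bu/Ex cutoffs themselves
are a per-dataset choice; by default they are placed at the tertiles
of the cohort's intensity distribution and are fully configurable,
optionally in units of sigma (the density standard deviation within
the hexamer region) to make them invariant under rescaling.

Volumes read and write the CCP4/MRC voxel-grid format (via gemmi) or
a plain-text dump used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class DensityVolume:
    """A 3D density grid, optionally with a hexamer region mask."""

    grid: np.ndarray
    voxel_size: float = 1.0
    region_mask: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        if not np.isfinite(self.grid).all():
            raise ValueError("density grid contains non-finite values")


@dataclass
class BinaryMask:
    grid: np.ndarray
    dilation_pixels: int
    source_threshold: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)


@dataclass
class ClassifierThresholds:
    """Overlap-intensity cutoffs delimiting the Bu / Un / Ex bands.

    ``bu_cutoffs`` are lower bounds on (I1, I2) for a buried call;
    ``ex_cutoffs`` are upper bounds for an exposed call.  The gap
    between them is the undefined band and must be non-empty.  If
    ``sigma_units`` is set the cutoffs are interpreted as multiples of
    the volume's sigma, making classification scale-invariant.
    """

    bu_cutoffs: tuple[float, float]
    ex_cutoffs: tuple[float, float]
    sigma_levels: tuple[float, float] = (2.0, 4.0)
    sigma_units: bool = False

    def __post_init__(self):
        if not (self.bu_cutoffs[0] > self.ex_cutoffs[0]
                and self.bu_cutoffs[1] > self.ex_cutoffs[1]):
            raise ValueError(
                "Bu lower bounds must exceed Ex upper bounds (non-empty Un band)"
            )


@dataclass
class ClassificationRecord:
    call: str
    i1: float
    i2: float
    sigma: float
    display_levels: dict


def _structuring_element(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def build_mask(
    reference_volumes: Sequence[DensityVolume],
    threshold: float,
    dilation: int,
    connectivity: int = 26,
) -> BinaryMask:
    """Average the reference volumes, binarize, and dilate.

    ``dilation`` voxels of growth "in all directions" uses the
    26-connected cube element by default (6-connectivity available).
    """
    if not reference_volumes:
        raise ValueError("at least one reference volume is required")
    shapes = {v.grid.shape for v in reference_volumes}
    if len(shapes) != 1:
        raise ValueError("reference volumes must share a grid shape")
    mean = np.mean([v.grid for v in reference_volumes], axis=0)
    white = mean > threshold
    if not white.any():
        raise ValueError("empty mask: no voxel exceeds the density threshold")
    if dilation > 0:
        white = ndimage.binary_dilation(
            white, structure=_structuring_element(connectivity), iterations=dilation
        )
    return BinaryMask(grid=white, dilation_pixels=dilation, source_threshold=threshold)


def overlap_intensity(volume: DensityVolume, mask: BinaryMask) -> float:
    """Masked density sum I_n = sum_i D_{i,n} M_i."""
    if volume.grid.shape != mask.grid.shape:
        raise ValueError("volume and mask shapes differ")
    return float(volume.grid[mask.grid].sum())


def volume_sigma(volume: DensityVolume) -> float:
    """Density standard deviation within the hexamer region.

    Uses ``region_mask`` when present, the whole grid otherwise.
    """
    if volume.region_mask is not None:
        return float(volume.grid[np.asarray(volume.region_mask, bool)].std())
    return float(volume.grid.std())


def classify(
    volume: DensityVolume,
    mask1: BinaryMask,
    mask2: BinaryMask,
    thresholds: ClassifierThresholds,
) -> ClassificationRecord:
    """Assign Bu / Ex / Un from the two overlap intensities.

    Bu iff both I1 and I2 reach their lower bounds; Ex iff both fall
    at or below their upper bounds; anything intermediate is Un.  Also
    reports sigma and the display density levels (2 sigma / 4 sigma by
    default) used for visual audit of borderline volumes.
    """
    i1 = overlap_intensity(volume, mask1)
    i2 = overlap_intensity(volume, mask2)
    sigma = volume_sigma(volume)
    scale = sigma if thresholds.sigma_units else 1.0
    if scale == 0.0:
        raise ValueError("zero sigma: cannot express cutoffs in sigma units")
    bu1, bu2 = (c * scale for c in thresholds.bu_cutoffs)
    ex1, ex2 = (c * scale for c in thresholds.ex_cutoffs)
    if i1 >= bu1 and i2 >= bu2:
        call = "Bu"
    elif i1 <= ex1 and i2 <= ex2:
        call = "Ex"
    else:
        call = "Un"
    levels = {f"{lv:g}sigma": lv * sigma for lv in thresholds.sigma_levels}
    return ClassificationRecord(call=call, i1=i1, i2=i2, sigma=sigma,
                                display_levels=levels)


def quantile_thresholds(
    i1_values: Sequence[float],
    i2_values: Sequence[float],
    lower: float = 1 / 3,
    upper: float = 2 / 3,
) -> ClassifierThresholds:
    """Cutoffs at cohort quantiles (tertiles by default).

    The overlap cutoffs separating Bu/Un/Ex were set by inspection in
    the original analysis and are not portable numbers; quantiles of
    the observed intensity distribution give a reasonable default that
    adapts to any cohort.
    """
    i1 = np.asarray(i1_values, float)
    i2 = np.asarray(i2_values, float)
    return ClassifierThresholds(
        bu_cutoffs=(float(np.quantile(i1, upper)), float(np.quantile(i2, upper))),
        ex_cutoffs=(float(np.quantile(i1, lower)), float(np.quantile(i2, lower))),
    )


def classify_cohort(
    volumes: Sequence[DensityVolume],
    mask1: BinaryMask,
    mask2: BinaryMask,
    thresholds: ClassifierThresholds | None = None,
) -> pd.DataFrame:
    """Classify a cohort; thresholds default to the cohort tertiles."""
    i1 = [overlap_intensity(v, mask1) for v in volumes]
    i2 = [overlap_intensity(v, mask2) for v in volumes]
    if thresholds is None:
        thresholds = quantile_thresholds(i1, i2)
    records = [classify(v, mask1, mask2, thresholds) for v in volumes]
    return pd.DataFrame(
        {
            "volume_id": np.arange(len(volumes)),
            "I1": [r.i1 for r in records],
            "I2": [r.i2 for r in records],
            "sigma": [r.sigma for r in records],
            "call": [r.call for r in records],
        }
    )


# ---------------------------------------------------------------------------
# I/O


def write_map(path: str | Path, volume: DensityVolume) -> None:
    """Write a volume in CCP4/MRC format."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.grid, dtype=np.float32))
    a = volume.voxel_size * volume.grid.shape[0]
    b = volume.voxel_size * volume.grid.shape[1]
    c = volume.voxel_size * volume.grid.shape[2]
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path) -> DensityVolume:
    """Read a CCP4/MRC map into a DensityVolume."""
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = np.array(ccp4.grid, copy=True, dtype=float)
    voxel = ccp4.grid.unit_cell.a / ccp4.grid.shape[0] if ccp4.grid.shape[0] else 1.0
    return DensityVolume(grid=grid, voxel_size=voxel)


def write_volume_txt(path: str | Path, volume: DensityVolume) -> None:
    """Plain-text dump: a shape header line then one value per line."""
    with open(path, "w") as fh:
        fh.write("# shape\t%d\t%d\t%d\tvoxel\t%.12g\n"
                 % (*volume.grid.shape, volume.voxel_size))
        np.savetxt(fh, volume.grid.ravel(), fmt="%.12g")


def read_volume_txt(path: str | Path) -> DensityVolume:
    with open(path) as fh:
        header = fh.readline().split("\t")
        shape = tuple(int(x) for x in header[1:4])
        voxel = float(header[5])
        values = np.loadtxt(fh)
    return DensityVolume(grid=values.reshape(shape), voxel_size=voxel)
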