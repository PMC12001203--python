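"""Stereochemistry assignment from replicate event-map densities.

A racemic crude mixture soaked into crystals leaves the modelled methyl
position ambiguous: the map protrusion could sit at either enantiomer's
methyl carbon.  For each replicate structure the density is sampled along
the candidate carbon-carbon bond (ring carbon to methyl carbon) for both
hypotheses, reduced to the mean of the positive samples, and the paired
differences across replicates are tested with a paired Student t-test.
Individual maps are rarely conclusive; the replicate vote is.

Maps are read and written as CCP4/MRC volumes via :mod:`gemmi`; this layer
consumes event maps, it does not compute them.  Only orthogonal cells are
supported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import t as t_dist

__all__ = [
    "BondProbe",
    "DensityGrid",
    "DensityProfile",
    "ProbeOutsideGridError",
    "ReplicateSet",
    "StereoCall",
    "call_enantiomer",
    "paired_t",
    "read_ccp4",
    "read_probes_json",
    "sample_bond_density",
    "write_ccp4",
]

DEFAULT_N_SAMPLES = 41
DEFAULT_ALPHA = 0.01


class ProbeOutsideGridError(ValueError):
    """A probe endpoint falls outside the map extent."""


@dataclass
class DensityGrid:
    """A 3D density volume on an orthogonal grid.

    ``values[i, j, k]`` sits at Cartesian position
    ``origin + (i, j, k) * spacing`` (Å); ``spacing`` is the voxel pitch per
    axis.
    """

    values: np.ndarray
    spacing: np.ndarray  # (3,) Å per voxel
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 3D with at least 2 points per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density grid contains non-finite values")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def cell(self) -> np.ndarray:
        """Orthogonal cell edge lengths in Å."""
        return self.spacing * np.array(self.values.shape)

    def to_grid_coords(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing


@dataclass(frozen=True)
class BondProbe:
    """Sampling segment from a ring carbon ``a`` to a candidate methyl ``b``."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    n_samples: int = DEFAULT_N_SAMPLES

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if np.allclose(self.a, self.b):
            raise ValueError("probe endpoints coincide")

    def points(self) -> np.ndarray:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        t = np.linspace(0.0, 1.0, self.n_samples)
        return a[None, :] + t[:, None] * (b - a)[None, :]


@dataclass(frozen=True)
class DensityProfile:
    """Interpolated densities along a bond and their positive-part mean."""

    samples: np.ndarray
    mean_positive: float


@dataclass(frozen=True)
class ReplicateSet:
    """Paired mean-positive densities (R hypothesis, S hypothesis), one pair
    per replicate structure."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError(
                "at least two replicate structures are required: a single "
                "structure cannot be called"
            )


@dataclass(frozen=True)
class StereoCall:
    call: str  # "R" | "S" | "inconclusive"
    t_stat: float
    df: int
    p_value: float
    alpha: float
    alternative: str
    degenerate: bool = False


# ---------------------------------------------------------------------------
# sampling

def sample_bond_density(grid: DensityGrid, probe: BondProbe) -> DensityProfile:
    """Trilinear density profile along a bond probe.

    Samples ``n_samples`` evenly spaced points including both endpoints and
    reduces them to the mean over strictly positive samples (0 when no
    sample is positive).
    """
    points = probe.points()
    coords = grid.to_grid_coords(points)
    upper = np.array(grid.values.shape) - 1
    for name, endpoint in (("a", coords[0]), ("b", coords[-1])):
        if np.any(endpoint < 0) or np.any(endpoint > upper):
            raise ProbeOutsideGridError(
                f"probe endpoint {name} at grid coordinates {np.round(endpoint, 3).tolist()} "
                f"lies outside grid of shape {grid.values.shape}"
            )
    samples = map_coordinates(grid.values.astype(float), coords.T, order=1, mode="nearest")
    positive = samples[samples > 0]
    mean_positive = float(positive.mean()) if positive.size else 0.0
    return DensityProfile(samples=samples, mean_positive=mean_positive)


# ---------------------------------------------------------------------------
# the paired test and the call

def paired_t(pairs: Sequence[tuple[float, float]]) -> tuple[float, int, float]:
    """One-sided paired Student t-test on differences d_i = r_i - s_i.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d)/sqrt(k))`` (sample sd,
    k-1 denominator), ``df = k - 1`` and ``p`` the upper-tail probability
    (alternative: the first column exceeds the second).

    Degenerate inputs: zero spread with non-zero mean gives infinite t and
    p = 0; zero spread with zero mean gives t = 0, p = 0.5.
    """
    d = np.array([r - s for r, s in pairs], dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("paired test needs at least two pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    df = k - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 0.5
        return math.copysign(math.inf, mean), df, 0.0 if mean > 0 else 1.0
    t = mean / (sd / math.sqrt(k))
    p = float(t_dist.sf(t, df))
    return float(t), df, p


def call_enantiomer(replicates: ReplicateSet, alpha: float = DEFAULT_ALPHA,
                    alternative: str = "one-sided") -> StereoCall:
    """Decide between enantiomers from replicate paired profiles.

    With the default ``one-sided`` mode the mirrored one-sided hypotheses are
    each tested at ``alpha``: R is called when P(T >= t) < alpha, S when
    P(T <= t) < alpha (one computation suffices; the two tests are mirror
    images).  ``two-sided`` calls the sign of t only when the two-sided
    p-value is below ``alpha``, which bounds the family-wise false-call rate
    by ``alpha`` itself.
    """
    if alternative not in ("one-sided", "two-sided"):
        raise ValueError("alternative must be 'one-sided' or 'two-sided'")
    t, df, p_upper = paired_t(replicates.pairs)
    degenerate = not math.isfinite(t)
    p_lower = 0.5 if degenerate and p_upper == 0.5 else 1.0 - p_upper
    if alternative == "one-sided":
        if p_upper < alpha:
            return StereoCall("R", t, df, p_upper, alpha, alternative, degenerate)
        if p_lower < alpha:
            return StereoCall("S", t, df, p_lower, alpha, alternative, degenerate)
        return StereoCall("inconclusive", t, df, min(p_upper, p_lower), alpha,
                          alternative, degenerate)
    p_two = 2.0 * min(p_upper, p_lower)
    if p_two < alpha:
        return StereoCall("R" if t > 0 else "S", t, df, p_two, alpha,
                          alternative, degenerate)
    return StereoCall("inconclusive", t, df, p_two, alpha, alternative, degenerate)


# ---------------------------------------------------------------------------
# CCP4/MRC I/O

def write_ccp4(grid: DensityGrid, path: str | Path) -> None:
    """Write an orthogonal-cell CCP4/MRC map (origin stored in the MRC
    ORIGIN header words, Å)."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    cell = grid.cell
    ccp4.grid.unit_cell = gemmi.UnitCell(cell[0], cell[1], cell[2], 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for axis, word in zip(range(3), (50, 51, 52)):
        ccp4.set_header_float(word, float(grid.origin[axis]))
    ccp4.write_ccp4_map(str(path))


def read_ccp4(path: str | Path) -> DensityGrid:
    """Read a CCP4/MRC map into a :class:`DensityGrid` (orthogonal cells only)."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    cell = ccp4.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError(f"{path}: only orthogonal cells are supported "
                         f"(angles {cell.alpha}, {cell.beta}, {cell.gamma})")
    values = np.array(ccp4.grid, copy=True)
    shape = values.shape
    spacing = np.array([cell.a, cell.b, cell.c]) / np.array(shape)
    origin = np.array([ccp4.header_float(word) for word in (50, 51, 52)])
    return DensityGrid(values=values, spacing=spacing, origin=origin)


def read_probes_json(path: str | Path) -> dict[str, BondProbe]:
    """Probe definitions: ``{"R": {"a": [x,y,z], "b": [x,y,z]}, "S": ...}``
    with an optional top-level ``n_samples``."""
    doc = json.loads(Path(path).read_text())
    n_samples = int(doc.get("n_samples", DEFAULT_N_SAMPLES))
    probes = {}
    for key in ("R", "S"):
        raw = doc[key]
        probes[key] = BondProbe(a=tuple(raw["a"]), b=tuple(raw["b"]), n_samples=n_samples)
    return probes
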