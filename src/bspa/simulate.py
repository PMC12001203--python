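"""Synthetic labelled data: LC-MS campaigns and density-map fixtures.

Every downstream layer is testable without an instrument: this module
generates (a) centroided MS1 chromatogram runs in which a known subset of
samples carries its expected product ion — with Gaussian elution profiles, a
carbon-isotopologue envelope, and random decoy signals — and (b) replicate
density grids containing a methyl-sized signal blob at one of the two
candidate enantiomer positions plus white noise.

The LC-MS model is deliberately stylised: carbon-only isotope envelopes
(binomial over the carbon count), no tailing or drift, no ion suppression.
That is adequate to exercise ±0.3 Da expected-ion matching, not to emulate a
particular instrument.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import binom

from .chem import AdductRule, ProductTarget, STANDARD_ADDUCTS, parse_formula
from .constants import C13_ABUNDANCE, C13_MASS_SHIFT
from .density import BondProbe, DensityGrid
from .mzml_io import write_mzml
from .qc import ChromatogramRun, QCVerdict, SpectrumScan

__all__ = [
    "CampaignEvaluation",
    "NoiseModel",
    "SimulatedCampaign",
    "SpeciesSpec",
    "default_rt_grid",
    "evaluate",
    "isotope_envelope",
    "make_campaign",
    "simulate_density_pair",
    "simulate_density_replicates",
    "simulate_run",
]

# decoy m/z window (Da) of the synthetic instrument
MZ_RANGE = (100.0, 1000.0)
MAX_ISOTOPOLOGUES = 8


@dataclass(frozen=True)
class SpeciesSpec:
    """One eluting species: a neutral mass with adducts and a Gaussian
    chromatographic profile."""

    target_id: str
    neutral_mass: float
    adducts: tuple[AdductRule, ...] = (STANDARD_ADDUCTS["[M+H]+"],)
    rt_apex: float = 150.0
    rt_sigma: float = 8.0
    abundance: float = 2e5
    n_carbons: int = 12

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Background model: decoy ions at uniform random m/z.

    ``baseline`` is the mean decoy intensity, ``jitter_sd`` its spread and
    ``decoy_density`` the expected number of decoys per spectrum.  The
    spiked-signal to baseline ratio of the default campaign is
    ``abundance / baseline`` = 10.
    """

    baseline: float = 2e4
    jitter_sd: float = 5e3
    decoy_density: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")


def default_rt_grid() -> np.ndarray:
    """5 s MS1 scans over a 300 s gradient."""
    return np.arange(0.0, 305.0, 5.0)


def isotope_envelope(n_carbons: int, max_k: int = MAX_ISOTOPOLOGUES) -> np.ndarray:
    """Relative isotopologue abundances M, M+1, ... (binomial carbon model:
    each carbon is 13C with probability 0.0107)."""
    k = np.arange(0, min(n_carbons, max_k) + 1)
    return binom.pmf(k, n_carbons, C13_ABUNDANCE)


def simulate_run(
    species: Sequence[SpeciesSpec],
    noise: NoiseModel,
    rt_grid: np.ndarray | None = None,
    sample_id: str = "sim",
) -> ChromatogramRun:
    """Simulate one centroided MS1 run.

    Each species contributes, at every scan, its adduct isotopologue ladder
    scaled by ``abundance * exp(-(rt - apex)^2 / (2 sigma^2))``; decoy counts
    per scan are Poisson(``decoy_density``) at uniform random m/z.  Output is
    deterministic under the noise model's seed.
    """
    rt_grid = default_rt_grid() if rt_grid is None else np.asarray(rt_grid, dtype=float)
    for sp in species:
        if sp.rt_apex - 4 * sp.rt_sigma < rt_grid[0] or sp.rt_apex + 4 * sp.rt_sigma > rt_grid[-1]:
            raise ValueError(
                f"species {sp.target_id!r}: rt grid must cover apex +/- 4 sigma"
            )
    rng = np.random.default_rng(noise.seed)
    scans = []
    for rt in rt_grid:
        mz_parts: list[np.ndarray] = []
        int_parts: list[np.ndarray] = []
        for sp in species:
            gauss = sp.abundance * math.exp(-((rt - sp.rt_apex) ** 2) / (2 * sp.rt_sigma**2))
            if gauss < 1e-6 * sp.abundance:
                continue
            envelope = isotope_envelope(sp.n_carbons)
            for adduct in sp.adducts:
                base_mz = adduct.mz(sp.neutral_mass)
                shifts = np.arange(envelope.size) * C13_MASS_SHIFT / abs(adduct.charge)
                mz_parts.append(base_mz + shifts)
                int_parts.append(gauss * envelope)
        n_decoys = rng.poisson(noise.decoy_density)
        if n_decoys:
            decoy_mz = rng.uniform(*MZ_RANGE, size=n_decoys)
            decoy_int = np.abs(rng.normal(noise.baseline, noise.jitter_sd, size=n_decoys))
            mz_parts.append(decoy_mz)
            int_parts.append(decoy_int)
        if mz_parts:
            mz = np.concatenate(mz_parts)
            intensity = np.concatenate(int_parts)
            mz, inverse = np.unique(mz, return_inverse=True)
            intensity = np.bincount(inverse, weights=intensity, minlength=mz.size)
        else:
            mz = np.array([])
            intensity = np.array([])
        scans.append(SpectrumScan(rt=float(rt), mz=mz, intensity=intensity, ms_level=1))
    return ChromatogramRun(sample_id=sample_id, scans=tuple(scans),
                           metadata={"generator": "bspa.simulate"})


@dataclass
class SimulatedCampaign:
    runs: list[ChromatogramRun]
    truth: pd.DataFrame  # sample_id, target_id, spiked


def make_campaign(
    n_samples: int,
    spike_fraction: float,
    targets: Sequence[ProductTarget],
    noise: NoiseModel | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    rt_grid: np.ndarray | None = None,
    abundance: float = 2e5,
    rt_sigma: float = 8.0,
) -> SimulatedCampaign:
    """Simulate a labelled campaign of ``n_samples`` runs.

    ``ceil(n_samples * spike_fraction)`` runs carry their assigned target's
    [M+H]+ species at a random apex; every run carries decoys.  Identical
    seeds give byte-identical campaigns (including written mzML files).
    """
    if not 0 <= spike_fraction <= 1:
        raise ValueError("spike_fraction must be in [0, 1]")
    if not targets:
        raise ValueError("at least one target is required")
    noise = noise or NoiseModel()
    rt_grid = default_rt_grid() if rt_grid is None else np.asarray(rt_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_spiked = math.ceil(n_samples * spike_fraction)
    spiked_flags = np.zeros(n_samples, dtype=bool)
    spiked_flags[rng.permutation(n_samples)[:n_spiked]] = True

    runs = []
    rows = []
    for i in range(n_samples):
        sample_id = f"S{i:04d}"
        target = targets[i % len(targets)]
        species: list[SpeciesSpec] = []
        if spiked_flags[i]:
            apex = float(rng.uniform(rt_grid[0] + 60.0, rt_grid[-1] - 60.0))
            n_carbons = parse_formula(target.formula).get("C", 0)
            species.append(SpeciesSpec(
                target_id=target.id,
                neutral_mass=target.mono_mass,
                rt_apex=apex,
                rt_sigma=rt_sigma,
                abundance=abundance,
                n_carbons=n_carbons,
            ))
        sample_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,))
                          .generate_state(1)[0] % (2**31))
        sample_noise = NoiseModel(baseline=noise.baseline, jitter_sd=noise.jitter_sd,
                                  decoy_density=noise.decoy_density, seed=sample_seed)
        runs.append(simulate_run(species, sample_noise, rt_grid, sample_id=sample_id))
        rows.append({"sample_id": sample_id, "target_id": target.id,
                     "spiked": bool(spiked_flags[i])})
    truth = pd.DataFrame(rows)
    campaign = SimulatedCampaign(runs=runs, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for run in runs:
            write_mzml(out / f"{run.sample_id}.mzML", run.sample_id, run.scans)
        truth.to_csv(out / "truth.csv", index=False)
    return campaign


@dataclass(frozen=True)
class CampaignEvaluation:
    recall: float
    precision: float
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def false_positive_rate(self) -> float:
        negatives = self.fp + self.tn
        return self.fp / negatives if negatives else float("nan")


def evaluate(verdicts: Sequence[QCVerdict], truth: pd.DataFrame) -> CampaignEvaluation:
    """Score machine verdicts against simulation truth (truth plays the role
    of the human label: TP = success & spiked, and so on)."""
    verdict_by_id = {v.sample_id: v for v in verdicts}
    truth_ids = set(truth["sample_id"])
    if set(verdict_by_id) != truth_ids:
        missing = truth_ids.symmetric_difference(verdict_by_id)
        raise ValueError(f"sample ids do not align; mismatched: {sorted(missing)[:5]}")
    tp = tn = fp = fn = 0
    for row in truth.itertuples():
        success = verdict_by_id[row.sample_id].status == "success"
        if row.spiked and success:
            tp += 1
        elif row.spiked:
            fn += 1
        elif success:
            fp += 1
        else:
            tn += 1
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return CampaignEvaluation(recall=recall, precision=precision, tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# density-grid fixtures

#: Synthetic map defaults: voxel pitch (Å), blob width (Å), C-C bond length
#: (Å) and the half-angle between the two candidate methyl directions
#: (tetrahedral geometry: the full angle is ~109.5°).
MAP_SPACING = 0.15
BLOB_SIGMA = 0.9
BOND_LENGTH = 1.54
MIRROR_HALF_ANGLE_DEG = 54.75
MAP_SHAPE = (61, 61, 61)

# fixed generic orientation of the molecular frame: axis-aligned bonds
# interact pathologically with the voxel lattice
_FRAME_ROTATION = Rotation.from_euler("xyz", [33.0, 57.0, 21.0], degrees=True).as_matrix()


def _pair_geometry(spacing: float, shape: tuple[int, int, int]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ring-carbon position and the two candidate methyl positions (Å)."""
    centre = (np.array(shape) - 1) * spacing / 2.0
    ring_c = centre + np.array([0.033, 0.071, 0.049])
    half = math.radians(MIRROR_HALF_ANGLE_DEG)
    v_r = np.array([BOND_LENGTH * math.cos(half), 0.0, BOND_LENGTH * math.sin(half)])
    v_s = np.array([BOND_LENGTH * math.cos(half), 0.0, -BOND_LENGTH * math.sin(half)])
    return ring_c, ring_c + _FRAME_ROTATION @ v_r, ring_c + _FRAME_ROTATION @ v_s


def simulate_density_pair(
    true_site: str,
    effect: float,
    noise_sd: float,
    grid_shape: tuple[int, int, int] = MAP_SHAPE,
    seed: int = 0,
    spacing: float = MAP_SPACING,
    blob_sigma: float = BLOB_SIGMA,
    n_samples: int = 41,
) -> tuple[DensityGrid, dict[str, BondProbe]]:
    """One replicate event-map fixture plus probes for both hypotheses.

    The grid holds a Gaussian blob of peak height ``effect`` centred on the
    true enantiomer's methyl carbon plus white noise N(0, ``noise_sd``);
    probes run from the shared ring carbon to each candidate methyl.
    """
    if true_site not in ("R", "S"):
        raise ValueError("true_site must be 'R' or 'S'")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    ring_c, me_r, me_s = _pair_geometry(spacing, grid_shape)
    centre = me_r if true_site == "R" else me_s
    ax = [np.arange(n) * spacing for n in grid_shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    d2 = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2
    values = effect * np.exp(-d2 / (2 * blob_sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=grid_shape)
    grid = DensityGrid(values=values.astype(np.float32),
                       spacing=np.full(3, spacing))
    probes = {
        "R": BondProbe(a=tuple(ring_c), b=tuple(me_r), n_samples=n_samples),
        "S": BondProbe(a=tuple(ring_c), b=tuple(me_s), n_samples=n_samples),
    }
    return grid, probes


def simulate_density_replicates(
    true_site: str, effect: float, noise_sd: float, k: int, seed: int = 0, **kwargs
) -> list[tuple[DensityGrid, dict[str, BondProbe]]]:
    """``k`` replicate map fixtures with independent noise."""
    out = []
    for i in range(k):
        rep_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,))
                       .generate_state(1)[0] % (2**31))
        out.append(simulate_density_pair(true_site, effect, noise_sd,
                                         seed=rep_seed, **kwargs))
    return out
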