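"""MSCheck-style LCMS quality control of crude reaction mixtures.

A crude reaction mixture (CRM) sample "succeeds" when the expected molecular
ion of its intended product can be found in the run: the total ion
chromatogram (TIC) is scanned for peaks, the mass spectra under each peak are
aggregated, and the aggregate is searched for signals within an m/z tolerance
of each expected adduct ion.  The machine verdict is reconciled against the
chemist's yes/no annotation into confusion categories, and per-iteration
reports aggregate into campaign summaries whose total percentage columns are
arithmetic means of the per-iteration percentages (count columns are sums).

Matched ions that are not the most intense signal of the peak spectrum are
flagged (``confidence="minor"``) but still count as success: in review these
are the cases a human analyst accepts while a rank-only reading would reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chem import AdductRule, ProductTarget, STANDARD_ADDUCTS
from .mzml_io import MzmlParseError, iter_spectra

__all__ = [
    "ChromatogramRun",
    "IonMatch",
    "IterationReport",
    "MzmlError",
    "ProfileModeError",
    "QCConfig",
    "QCVerdict",
    "SpectrumScan",
    "SummaryReport",
    "TICPeak",
    "assign_verdict",
    "compute_tic",
    "find_tic_peaks",
    "iteration_report",
    "match_expected",
    "peak_spectrum",
    "read_run",
    "reconcile",
    "round_half_up",
    "run_qc",
    "summarize",
    "write_report",
]


class MzmlError(ValueError):
    """The mzML input is malformed or empty."""


class ProfileModeError(MzmlError):
    """Profile-mode spectra require centroiding upstream."""


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the rounding used in printed report tables)."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class SpectrumScan:
    rt: float  # seconds
    mz: np.ndarray  # ascending
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z array must be strictly ascending")
        if not np.all(np.isfinite(intensity)) or np.any(intensity < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class ChromatogramRun:
    sample_id: str
    scans: tuple[SpectrumScan, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [scan.rt for scan in self.scans]
        if rts != sorted(rts):
            raise ValueError("scans must be ordered by retention time")
        if not any(scan.ms_level == 1 for scan in self.scans):
            raise MzmlError(f"run {self.sample_id!r}: no MS1 scans")

    def ms1_scans(self) -> tuple[SpectrumScan, ...]:
        return tuple(scan for scan in self.scans if scan.ms_level == 1)


@dataclass(frozen=True)
class TICPeak:
    apex_rt: float
    apex_index: int
    prominence: float
    left_index: int
    right_index: int  # half-open

    def __post_init__(self) -> None:
        if not (self.left_index <= self.apex_index < self.right_index):
            raise ValueError("peak bounds must satisfy left <= apex < right")
        if self.prominence <= 0:
            raise ValueError("prominence must be positive")


@dataclass(frozen=True)
class IonMatch:
    target_id: str
    adduct: str
    expected_mz: float
    observed_mz: float
    intensity: float
    rank: int  # 1-based intensity rank within the peak spectrum
    within_tol: bool
    most_prominent: bool


@dataclass(frozen=True)
class QCVerdict:
    sample_id: str
    status: str  # "success" | "fail"
    confidence: str  # "prominent" | "minor" | ""
    matches: tuple[IonMatch, ...]
    human_label: str | None = None  # "yes" | "no"
    note: str = ""


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the automated QC.

    The 0.3 Da default tolerance corresponds to unit-resolution LC-MS as
    used for reaction monitoring; peak thresholds are fractions of the TIC
    maximum so configs transfer across instruments.  ``noise_quantile``
    implements the "significant ion signal" requirement: a matched signal
    must exceed this quantile of all centroid intensities in the run (0
    disables the floor).
    """

    mz_tolerance: float = 0.3
    adducts: tuple[AdductRule, ...] = (STANDARD_ADDUCTS["[M+H]+"],)
    min_prominence_fraction: float = 0.05
    min_peak_width: int = 2
    spectrum_aggregation: str = "sum"  # "sum" | "apex"
    noise_quantile: float = 0.9

    def __post_init__(self) -> None:
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be positive")
        if not 0 < self.min_prominence_fraction < 1:
            raise ValueError("min_prominence_fraction must be in (0, 1)")
        if self.spectrum_aggregation not in ("sum", "apex"):
            raise ValueError("spectrum_aggregation must be 'sum' or 'apex'")
        if not 0 <= self.noise_quantile < 1:
            raise ValueError("noise_quantile must be in [0, 1)")


@dataclass(frozen=True)
class IterationReport:
    iteration: str
    n_samples: int
    match_pct: float  # % agreement of machine verdict with human label
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tp_plus_tn_pct: float = float("nan")
    fn_pct: float = float("nan")
    fp_pct: float = float("nan")


@dataclass(frozen=True)
class SummaryReport:
    per_iteration: tuple[IterationReport, ...]
    n_samples_total: int
    match_pct_total: float  # rounded, half-up at integer precision
    tp_total: int
    fn_total: int
    fp_total: int
    tp_plus_tn_pct_total: float
    fn_pct_total: float
    fp_pct_total: float
    raw_means: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mzML input

def read_run(path: str | Path, sample_id: str | None = None,
             assume_centroided: bool = False) -> ChromatogramRun:
    """Load the MS1 scans of an mzML run in retention-time order.

    MS2+ scans are ignored.  Profile-mode spectra raise
    :class:`ProfileModeError` unless ``assume_centroided`` is set (the QC
    pipeline operates on centroided data only).
    """
    path = Path(path)
    scans = []
    try:
        for spectrum in iter_spectra(path):
            if spectrum.ms_level != 1:
                continue
            if spectrum.is_profile and not assume_centroided:
                raise ProfileModeError(
                    f"{path.name}: profile-mode spectrum {spectrum.id!r}; "
                    "centroid the data upstream or pass assume_centroided=True"
                )
            if spectrum.rt_seconds is None:
                raise MzmlError(f"spectrum {spectrum.id!r}: missing scan start time")
            order = np.argsort(spectrum.mz, kind="stable")
            scans.append(SpectrumScan(
                rt=spectrum.rt_seconds,
                mz=spectrum.mz[order], intensity=spectrum.intensity[order],
                ms_level=1))
    except ProfileModeError:
        raise
    except MzmlParseError as exc:
        raise MzmlError(str(exc)) from exc
    if not scans:
        raise MzmlError(f"{path}: no MS1 scans found")
    scans.sort(key=lambda scan: scan.rt)
    return ChromatogramRun(
        sample_id=sample_id or path.stem,
        scans=tuple(scans),
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# TIC and peaks

def compute_tic(run: ChromatogramRun) -> tuple[np.ndarray, np.ndarray]:
    """Retention times and total ion current per MS1 scan."""
    scans = run.ms1_scans()
    rt = np.array([scan.rt for scan in scans])
    tic = np.array([float(scan.intensity.sum()) for scan in scans])
    return rt, tic


def find_tic_peaks(tic: np.ndarray, config: QCConfig,
                   rt: np.ndarray | None = None) -> list[TICPeak]:
    """Locate TIC peaks above the configured prominence and width.

    Prominence is thresholded at ``min_prominence_fraction`` of the TIC
    maximum; peak bounds are the prominence bases (half-open on the right).
    A flat or empty trace yields no peaks.
    """
    tic = np.asarray(tic, dtype=float)
    if tic.size < 3 or np.ptp(tic) == 0:
        return []
    prominence = config.min_prominence_fraction * tic.max()
    indices, props = find_peaks(tic, prominence=prominence, width=config.min_peak_width)
    peaks = []
    for i, apex in enumerate(indices):
        left = int(props["left_bases"][i])
        right = int(props["right_bases"][i]) + 1
        peaks.append(TICPeak(
            apex_rt=float(rt[apex]) if rt is not None else float(apex),
            apex_index=int(apex),
            prominence=float(props["prominences"][i]),
            left_index=left,
            right_index=right,
        ))
    return peaks


def peak_spectrum(run: ChromatogramRun, peak: TICPeak,
                  config: QCConfig) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate the mass spectra under a TIC peak.

    Under ``sum`` aggregation all centroids of the scans in
    ``[left_index, right_index)`` are pooled and merged into clusters no
    wider than half the m/z tolerance (summed intensity, intensity-weighted
    m/z); under ``apex`` the apex scan's spectrum is returned unchanged.
    """
    scans = run.ms1_scans()
    if peak.right_index > len(scans):
        raise ValueError("peak bounds outside run")
    if config.spectrum_aggregation == "apex":
        scan = scans[peak.apex_index]
        return scan.mz.copy(), scan.intensity.copy()
    window = scans[peak.left_index:peak.right_index]
    if not window or all(scan.mz.size == 0 for scan in window):
        return np.array([]), np.array([])
    mz = np.concatenate([scan.mz for scan in window])
    intensity = np.concatenate([scan.intensity for scan in window])
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    # greedy clustering: break where the gap exceeds tol/2
    breaks = np.flatnonzero(np.diff(mz) > config.mz_tolerance / 2) + 1
    groups = np.split(np.arange(mz.size), breaks)
    agg_mz = np.empty(len(groups))
    agg_int = np.empty(len(groups))
    for k, idx in enumerate(groups):
        weights = intensity[idx]
        total = weights.sum()
        agg_int[k] = total
        agg_mz[k] = np.average(mz[idx], weights=weights) if total > 0 else mz[idx].mean()
    return agg_mz, agg_int


# ---------------------------------------------------------------------------
# ion matching and verdicts

def match_expected(spectrum: tuple[np.ndarray, np.ndarray],
                   targets: Sequence[ProductTarget],
                   config: QCConfig,
                   intensity_floor: float = 0.0) -> list[IonMatch]:
    """Search an aggregated peak spectrum for each target's expected ions.

    For every (target, adduct) the most intense signal within the m/z
    tolerance is reported; its rank is the 1-based intensity rank within the
    whole peak spectrum.  Ions with no signal inside tolerance — or none
    above the significance floor — produce no match.
    """
    mz, intensity = spectrum
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        return []
    matches = []
    for target in targets:
        for adduct_name, expected_mz, _charge in target.expected_ions:
            inside = np.flatnonzero(
                (np.abs(mz - expected_mz) <= config.mz_tolerance)
                & (intensity > intensity_floor)
            )
            if inside.size == 0:
                continue
            best = inside[np.argmax(intensity[inside])]
            rank = 1 + int(np.count_nonzero(intensity > intensity[best]))
            matches.append(IonMatch(
                target_id=target.id,
                adduct=adduct_name,
                expected_mz=float(expected_mz),
                observed_mz=float(mz[best]),
                intensity=float(intensity[best]),
                rank=rank,
                within_tol=True,
                most_prominent=rank == 1,
            ))
    return matches


def assign_verdict(sample_id: str, peaks: Sequence[TICPeak],
                   matches_per_peak: Sequence[Sequence[IonMatch]],
                   config: QCConfig) -> QCVerdict:
    """Success iff any TIC peak holds a within-tolerance expected-ion match.

    Confidence is ``prominent`` when some match is the base peak of its
    aggregated spectrum, else ``minor`` — matched-but-not-most-prominent is
    the category human review reclassifies as true positive.
    """
    all_matches = tuple(m for matches in matches_per_peak for m in matches if m.within_tol)
    if not peaks or not all_matches:
        return QCVerdict(sample_id=sample_id, status="fail", confidence="", matches=all_matches)
    confidence = "prominent" if any(m.most_prominent for m in all_matches) else "minor"
    return QCVerdict(sample_id=sample_id, status="success", confidence=confidence,
                     matches=all_matches)


def run_qc(run: ChromatogramRun, targets: Sequence[ProductTarget],
           config: QCConfig | None = None) -> QCVerdict:
    """Full per-sample pipeline: TIC -> peaks -> aggregated spectra -> verdict."""
    config = config or QCConfig()
    rt, tic = compute_tic(run)
    peaks = find_tic_peaks(tic, config, rt=rt)
    floor = noise_floor(run, config)
    matches_per_peak = [
        match_expected(peak_spectrum(run, peak, config), targets, config,
                       intensity_floor=floor)
        for peak in peaks
    ]
    return assign_verdict(run.sample_id, peaks, matches_per_peak, config)


def noise_floor(run: ChromatogramRun, config: QCConfig) -> float:
    """Significance floor: the configured quantile of all centroid
    intensities in the run's MS1 scans (0 when disabled or empty)."""
    if config.noise_quantile <= 0:
        return 0.0
    pooled = np.concatenate([scan.intensity for scan in run.ms1_scans()] or [np.array([])])
    if pooled.size == 0:
        return 0.0
    return float(np.quantile(pooled, config.noise_quantile))


def reconcile(verdict: QCVerdict, human_label: str | None = None) -> str:
    """Confusion category of a machine verdict against the human label."""
    label = human_label if human_label is not None else verdict.human_label
    if label not in ("yes", "no"):
        raise ValueError(f"sample {verdict.sample_id!r}: human label missing or invalid: {label!r}")
    machine_yes = verdict.status == "success"
    if machine_yes and label == "yes":
        return "TP"
    if not machine_yes and label == "no":
        return "TN"
    if machine_yes:
        return "FP"
    return "FN"


# ---------------------------------------------------------------------------
# reports

def iteration_report(iteration: str, verdicts: Sequence[QCVerdict],
                     labels: Mapping[str, str]) -> IterationReport:
    """Per-iteration agreement row from verdicts and human annotations."""
    cells = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    n_labeled = 0
    for verdict in verdicts:
        label = labels.get(verdict.sample_id, verdict.human_label)
        if label is None:
            continue
        n_labeled += 1
        cells[reconcile(verdict, label)] += 1
    if n_labeled == 0:
        raise ValueError(f"iteration {iteration!r}: no labelled samples")
    match_pct = 100.0 * (cells["TP"] + cells["TN"]) / n_labeled
    return IterationReport(
        iteration=iteration,
        n_samples=len(verdicts),
        match_pct=match_pct,
        tp=cells["TP"], fn=cells["FN"], fp=cells["FP"],
        tp_plus_tn_pct=match_pct,
        fn_pct=100.0 * cells["FN"] / n_labeled,
        fp_pct=100.0 * cells["FP"] / n_labeled,
    )


def summarize(iterations: Sequence[IterationReport]) -> SummaryReport:
    """Campaign summary: count columns sum; percentage columns are the
    arithmetic mean of the per-iteration percentages, rounded half-up to
    integer precision (raw means are retained alongside)."""
    if not iterations:
        raise ValueError("summarize() needs at least one iteration report")
    means = {
        "match_pct": float(np.mean([r.match_pct for r in iterations])),
        "tp_plus_tn_pct": float(np.mean([r.tp_plus_tn_pct for r in iterations])),
        "fn_pct": float(np.mean([r.fn_pct for r in iterations])),
        "fp_pct": float(np.mean([r.fp_pct for r in iterations])),
    }
    return SummaryReport(
        per_iteration=tuple(iterations),
        n_samples_total=sum(r.n_samples for r in iterations),
        match_pct_total=round_half_up(means["match_pct"]),
        tp_total=sum(r.tp for r in iterations),
        fn_total=sum(r.fn for r in iterations),
        fp_total=sum(r.fp for r in iterations),
        tp_plus_tn_pct_total=round_half_up(means["tp_plus_tn_pct"]),
        fn_pct_total=round_half_up(means["fn_pct"]),
        fp_pct_total=round_half_up(means["fp_pct"]),
        raw_means=means,
    )


def verdicts_frame(verdicts: Iterable[QCVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        best = min(v.matches, key=lambda m: m.rank, default=None)
        rows.append({
            "sample_id": v.sample_id,
            "status": v.status,
            "confidence": v.confidence,
            "n_matches": len(v.matches),
            "best_rank": best.rank if best else "",
            "observed_mz": f"{best.observed_mz:.4f}" if best else "",
            "human_label": v.human_label or "",
            "category": reconcile(v) if v.human_label in ("yes", "no") else "",
            "note": v.note,
        })
    return pd.DataFrame(rows)


def summary_frame(summary: SummaryReport) -> pd.DataFrame:
    rows = [{
        "iteration": r.iteration, "n_samples": r.n_samples,
        "match_pct": r.match_pct, "tp": r.tp, "fn": r.fn, "fp": r.fp,
        "tp_plus_tn_pct": r.tp_plus_tn_pct, "fn_pct": r.fn_pct, "fp_pct": r.fp_pct,
    } for r in summary.per_iteration]
    rows.append({
        "iteration": "total", "n_samples": summary.n_samples_total,
        "match_pct": summary.match_pct_total, "tp": summary.tp_total,
        "fn": summary.fn_total, "fp": summary.fp_total,
        "tp_plus_tn_pct": summary.tp_plus_tn_pct_total,
        "fn_pct": summary.fn_pct_total, "fp_pct": summary.fp_pct_total,
    })
    return pd.DataFrame(rows)


def write_report(out_dir: str | Path, verdicts: Sequence[QCVerdict],
                 summary: SummaryReport | None = None) -> None:
    """Write the verdict table and, if given, the campaign summary
    (CSV + JSON mirroring the summary's columns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    verdicts_frame(verdicts).to_csv(out / "verdicts.csv", index=False)
    if summary is not None:
        summary_frame(summary).to_csv(out / "summary.csv", index=False)
        payload = {
            "per_iteration": summary_frame(summary).to_dict(orient="records"),
            "totals": {
                "n_samples": summary.n_samples_total,
                "match_pct": summary.match_pct_total,
                "tp": summary.tp_total, "fn": summary.fn_total, "fp": summary.fp_total,
                "tp_plus_tn_pct": summary.tp_plus_tn_pct_total,
                "fn_pct": summary.fn_pct_total, "fp_pct": summary.fp_pct_total,
                "raw_means": dict(summary.raw_means),
            },
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2))


def with_labels(verdicts: Sequence[QCVerdict], labels: Mapping[str, str]) -> list[QCVerdict]:
    """Attach human annotations to verdicts by sample id."""
    return [replace(v, human_label=labels.get(v.sample_id, v.human_label)) for v in verdicts]
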