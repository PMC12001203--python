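"""Campaign accounting: funnel success rates and resource totals.

The screening funnel runs synthesis attempts -> LCMS-confirmed products ->
usable diffraction datasets -> product-bound structures; each stage rate is
the count over the previous stage's count.  Resource accounting contrasts
per-target manual synthesis figures (days, chromatography columns/work-ups,
solvent) with the automated workflow's totals; saving fractions are
automated/manual and the solvent fold-reduction is manual/automated.

Raw (unrounded) values are always retained in machine-readable output;
display rounding is half-up at the precision conventional for each figure.
Year conversion uses 365 days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .qc import SummaryReport, round_half_up, summary_frame

__all__ = [
    "FunnelRates",
    "ResourceRow",
    "ResourceSummary",
    "StageCounts",
    "funnel_rates",
    "render_reports",
    "resource_totals",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class StageCounts:
    """Counts at each funnel stage of a campaign."""

    attempted: int
    lcms_success: int
    datasets_usable: int
    product_bound: int
    starting_material_bound: int = 0

    def __post_init__(self) -> None:
        counts = (self.attempted, self.lcms_success, self.datasets_usable,
                  self.product_bound, self.starting_material_bound)
        if any(c < 0 for c in counts):
            raise ValueError("stage counts must be non-negative")
        if not (self.product_bound <= self.datasets_usable <= self.attempted):
            raise ValueError("expected product_bound <= datasets_usable <= attempted")


@dataclass(frozen=True)
class Rate:
    numerator: int
    denominator: int
    percent: float | None  # None when the denominator is zero
    display: str  # rounded half-up at the stage's display precision

    @staticmethod
    def of(numerator: int, denominator: int, ndigits: int) -> "Rate":
        if denominator == 0:
            return Rate(numerator, denominator, None, "undefined")
        pct = 100.0 * numerator / denominator
        rounded = round_half_up(pct, ndigits)
        display = f"{rounded:.{ndigits}f}%" if ndigits else f"{int(rounded)}%"
        return Rate(numerator, denominator, pct, display)


@dataclass(frozen=True)
class FunnelRates:
    lcms_rate: Rate  # LCMS successes / attempted syntheses
    usable_rate: Rate  # usable datasets / LCMS successes
    hit_rate: Rate  # product-bound structures / usable datasets


def funnel_rates(counts: StageCounts) -> FunnelRates:
    """Stage-over-stage success percentages of the campaign funnel.

    Display precision: whole percent for synthesis and dataset stages, one
    decimal for the crystallographic hit rate.  A zero denominator yields an
    undefined rate (never 0)."""
    return FunnelRates(
        lcms_rate=Rate.of(counts.lcms_success, counts.attempted, 0),
        usable_rate=Rate.of(counts.datasets_usable, counts.lcms_success, 0),
        hit_rate=Rate.of(counts.product_bound, counts.datasets_usable, 1),
    )


@dataclass(frozen=True)
class ResourceRow:
    """Per-iteration resource figures (manual per-target, automated totals)."""

    iteration: str
    n_targets: int
    manual_days_per_target: float
    auto_days_total: float
    manual_columns_per_target: float
    manual_solvent_per_target: float  # mL
    auto_solvent_per_target: float  # mL
    auto_columns_total: float = 0.0

    def __post_init__(self) -> None:
        values = (self.n_targets, self.manual_days_per_target, self.auto_days_total,
                  self.manual_columns_per_target, self.manual_solvent_per_target,
                  self.auto_solvent_per_target, self.auto_columns_total)
        if any(v < 0 for v in values):
            raise ValueError("resource figures must be non-negative")


@dataclass(frozen=True)
class ResourceSummary:
    n_targets: int
    manual_total_days: float
    manual_total_years: float
    auto_total_days: float
    manual_total_columns: float
    auto_total_columns: float
    manual_total_solvent_l: float
    auto_total_solvent_l: float
    saving_fraction_time_pct: float  # automated / manual * 100
    saving_fraction_columns_pct: float
    saving_fraction_solvent_pct: float
    fold_reduction_solvent: float  # manual / automated


def resource_totals(rows: Sequence[ResourceRow]) -> ResourceSummary:
    """Aggregate per-iteration resource rows into campaign totals.

    Manual totals scale per-target figures by the target count; solvent is
    reported in litres.  Saving fractions are automated/manual x 100; the
    solvent fold-reduction is manual/automated."""
    if not rows:
        raise ValueError("resource_totals() needs at least one row")
    manual_days = sum(r.n_targets * r.manual_days_per_target for r in rows)
    auto_days = sum(r.auto_days_total for r in rows)
    manual_columns = sum(r.n_targets * r.manual_columns_per_target for r in rows)
    auto_columns = sum(r.auto_columns_total for r in rows)
    manual_solvent_l = sum(r.n_targets * r.manual_solvent_per_target for r in rows) / 1000.0
    auto_solvent_l = sum(r.n_targets * r.auto_solvent_per_target for r in rows) / 1000.0

    def fraction(auto: float, manual: float) -> float:
        return 100.0 * auto / manual if manual else float("nan")

    return ResourceSummary(
        n_targets=sum(r.n_targets for r in rows),
        manual_total_days=manual_days,
        manual_total_years=manual_days / DAYS_PER_YEAR,
        auto_total_days=auto_days,
        manual_total_columns=manual_columns,
        auto_total_columns=auto_columns,
        manual_total_solvent_l=manual_solvent_l,
        auto_total_solvent_l=auto_solvent_l,
        saving_fraction_time_pct=fraction(auto_days, manual_days),
        saving_fraction_columns_pct=fraction(auto_columns, manual_columns),
        saving_fraction_solvent_pct=fraction(auto_solvent_l, manual_solvent_l),
        fold_reduction_solvent=(manual_solvent_l / auto_solvent_l
                                if auto_solvent_l else float("inf")),
    )


# ---------------------------------------------------------------------------
# rendering

def _markdown_table(frame: pd.DataFrame) -> str:
    headers = list(frame.columns)
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _funnel_frame(funnel: FunnelRates) -> pd.DataFrame:
    rows = []
    for stage, rate in (("lcms_success/attempted", funnel.lcms_rate),
                        ("datasets_usable/lcms_success", funnel.usable_rate),
                        ("product_bound/datasets_usable", funnel.hit_rate)):
        rows.append({"stage": stage, "numerator": rate.numerator,
                     "denominator": rate.denominator,
                     "percent_raw": "" if rate.percent is None else f"{rate.percent:.6f}",
                     "percent": rate.display})
    return pd.DataFrame(rows)


def _resources_frame(summary: ResourceSummary) -> pd.DataFrame:
    rows = [
        ("targets", summary.n_targets, summary.n_targets),
        ("time_days", summary.manual_total_days, summary.auto_total_days),
        ("time_years", summary.manual_total_years, summary.auto_total_days / DAYS_PER_YEAR),
        ("columns_workups", summary.manual_total_columns, summary.auto_total_columns),
        ("solvent_l", summary.manual_total_solvent_l, summary.auto_total_solvent_l),
    ]
    frame = pd.DataFrame(rows, columns=["quantity", "manual", "automated"])
    savings = pd.DataFrame([
        {"quantity": "saving_fraction_time_pct", "manual": "",
         "automated": round_half_up(summary.saving_fraction_time_pct, 1)},
        {"quantity": "saving_fraction_columns_pct", "manual": "",
         "automated": round_half_up(summary.saving_fraction_columns_pct, 1)},
        {"quantity": "saving_fraction_solvent_pct", "manual": "",
         "automated": round_half_up(summary.saving_fraction_solvent_pct, 1)},
        {"quantity": "fold_reduction_solvent", "manual": "",
         "automated": round_half_up(summary.fold_reduction_solvent, 1)},
    ])
    return pd.concat([frame, savings], ignore_index=True)


def render_reports(
    out_dir: str | Path,
    resources: ResourceSummary | None = None,
    funnel: FunnelRates | None = None,
    qc_summary: SummaryReport | None = None,
) -> dict[str, Path]:
    """Write the campaign report bundle (CSV + Markdown + JSON).

    Sections are optional; omitted sections still produce header-only files
    so downstream tooling sees a deterministic file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    md = ["# Campaign report", ""]

    funnel_frame = (_funnel_frame(funnel) if funnel is not None
                    else pd.DataFrame(columns=["stage", "numerator", "denominator",
                                               "percent_raw", "percent"]))
    path = out / "funnel.csv"
    funnel_frame.to_csv(path, index=False)
    written["funnel_csv"] = path
    md += ["## Screening funnel", "", _markdown_table(funnel_frame)]

    resources_frame = (_resources_frame(resources) if resources is not None
                       else pd.DataFrame(columns=["quantity", "manual", "automated"]))
    path = out / "resources.csv"
    resources_frame.to_csv(path, index=False)
    written["resources_csv"] = path
    md += ["## Resources: manual vs automated", "", _markdown_table(resources_frame)]

    qc_frame = (summary_frame(qc_summary) if qc_summary is not None
                else pd.DataFrame(columns=["iteration", "n_samples", "match_pct",
                                           "tp", "fn", "fp", "tp_plus_tn_pct",
                                           "fn_pct", "fp_pct"]))
    path = out / "qc_summary.csv"
    qc_frame.to_csv(path, index=False)
    written["qc_summary_csv"] = path
    md += ["## LCMS QC agreement", "", _markdown_table(qc_frame)]

    md_path = out / "report.md"
    md_path.write_text("\n".join(md))
    written["markdown"] = md_path

    payload: dict = {}
    if funnel is not None:
        payload["funnel"] = funnel_frame.to_dict(orient="records")
    if resources is not None:
        payload["resources"] = {
            "raw": resources.__dict__,
            "rounded": {
                "manual_total_years": round_half_up(resources.manual_total_years, 2),
                "manual_total_solvent_l": round_half_up(resources.manual_total_solvent_l, 1),
                "auto_total_solvent_l": round_half_up(resources.auto_total_solvent_l, 2),
                "fold_reduction_solvent": round_half_up(resources.fold_reduction_solvent, 1),
            },
        }
    if qc_summary is not None:
        payload["qc"] = qc_frame.to_dict(orient="records")
    json_path = out / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, default=float))
    written["json"] = json_path
    return written
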