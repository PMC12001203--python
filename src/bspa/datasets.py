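"""Published figures of the PHIP(2) fragment-elaboration campaign.

These tables are the printed inputs of the campaign report layer: the
per-iteration LCMS QC agreement between the automated analysis and the human
annotation, the per-iteration resource comparison between manual and robotic
synthesis, and the screening-funnel counts.  They are inputs to the
accounting operations, not recomputed quantities.

Iteration 1.1's QC comparison was never completed and is therefore absent
from the agreement table (five evaluated iterations).  Iteration 3's 512
samples include 448 analysed by the automated tool.
"""

from __future__ import annotations

from .qc import IterationReport
from .report import ResourceRow, StageCounts

__all__ = ["PHIP2_FUNNEL", "PHIP2_QC_ROWS", "PHIP2_RESOURCE_ROWS"]

#: Per-iteration agreement of the automated QC with the human annotation,
#: and the post-review confusion categories (counts and percentages).
PHIP2_QC_ROWS: tuple[IterationReport, ...] = (
    IterationReport(iteration="1", n_samples=58, match_pct=81,
                    tp=4, fn=7, fp=0, tp_plus_tn_pct=88, fn_pct=12, fp_pct=0),
    IterationReport(iteration="2", n_samples=64, match_pct=96.87,
                    tp=0, fn=2, fp=0, tp_plus_tn_pct=97, fn_pct=2, fp_pct=0),
    IterationReport(iteration="3", n_samples=512, match_pct=78.1,
                    tp=66, fn=12, fp=20, tp_plus_tn_pct=93, fn_pct=3, fp_pct=4),
    IterationReport(iteration="3.5", n_samples=1024, match_pct=74.4,
                    tp=172, fn=30, fp=55, tp_plus_tn_pct=91, fn_pct=3, fp_pct=5),
    IterationReport(iteration="4.2", n_samples=160, match_pct=84.4,
                    tp=1, fn=16, fp=8, tp_plus_tn_pct=85, fn_pct=10, fp_pct=5),
)

#: Manual-vs-automated resource figures per iteration.  Solvent is mL per
#: target; automated days and columns are whole-iteration totals.
PHIP2_RESOURCE_ROWS: tuple[ResourceRow, ...] = (
    ResourceRow("1", 58, manual_days_per_target=3, auto_days_total=3,
                manual_columns_per_target=1, auto_columns_total=1,
                manual_solvent_per_target=1000, auto_solvent_per_target=5),
    ResourceRow("1.1", 58, manual_days_per_target=3, auto_days_total=3,
                manual_columns_per_target=1, auto_columns_total=1,
                manual_solvent_per_target=1000, auto_solvent_per_target=5),
    ResourceRow("2", 64, manual_days_per_target=1, auto_days_total=2,
                manual_columns_per_target=1, auto_columns_total=1,
                manual_solvent_per_target=1000, auto_solvent_per_target=5),
    ResourceRow("3", 512, manual_days_per_target=5, auto_days_total=4,
                manual_columns_per_target=2, auto_columns_total=2,
                manual_solvent_per_target=2500, auto_solvent_per_target=10),
    ResourceRow("3.5", 1024, manual_days_per_target=5, auto_days_total=4,
                manual_columns_per_target=2, auto_columns_total=2,
                manual_solvent_per_target=2500, auto_solvent_per_target=10),
    ResourceRow("4.2", 160, manual_days_per_target=8, auto_days_total=4,
                manual_columns_per_target=3, auto_columns_total=3,
                manual_solvent_per_target=4500, auto_solvent_per_target=15),
)

#: Screening-funnel counts: attempted syntheses, LCMS-confirmed products,
#: usable diffraction datasets, and bound structures.
PHIP2_FUNNEL = StageCounts(
    attempted=1876,
    lcms_success=1077,
    datasets_usable=969,
    product_bound=22,
    starting_material_bound=7,
)
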