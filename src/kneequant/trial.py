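"""Longitudinal trial analysis as a model/results pair.

`CartilageTrialModel` is built from a tidy per-patient metrics table (or an
already-computed alteration table) and, on `fit()`, produces a
`CartilageTrialResults` holding the before/after alterations, the paired
exact Wilcoxon tests comparing them, each column's test against zero,
median/IQR summaries, and a formatted wide summary table in the layout such
trials report (patients as rows, region x period as columns, median /
quartiles / p underneath).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Optional, Sequence

import pandas as pd

from . import stats as kqstats
from .stats import (
    AlterationTable,
    SummaryStats,
    WilcoxonResult,
    compute_alterations,
    round_half_even,
    summarize,
    wilcoxon_signed_rank,
)

__all__ = ["CartilageTrialModel", "CartilageTrialResults", "ANALYZED_REGIONS"]

#: the regions entering the longitudinal analysis (the anterior femoral
#: quadrants are computed by the pipeline but sit under the patella and are
#: conventionally excluded from tibiofemoral OA progression analysis)
ANALYZED_REGIONS = (
    ("femur", "posteromedial"),
    ("femur", "posterolateral"),
    ("tibia", "medial"),
    ("tibia", "lateral"),
)

METRIC_LABELS = {
    "area_ratio": "Projected cartilage area ratio (thickness >= 1.5 mm)",
    "mean_thickness_mm": "Thickness (mm)",
}


class CartilageTrialModel:
    """Before/after alteration analysis of a longitudinal metrics table.

    Parameters
    ----------
    records
        Tidy frame with columns patient_id, timepoint_weeks, bone, region,
        metric, value covering the baseline, pre-treatment and
        post-treatment scans of each patient.
    regions, metrics
        Which (bone, region) pairs and metrics to analyse.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        regions: Sequence[tuple[str, str]] = ANALYZED_REGIONS,
        metrics: Sequence[str] = ("area_ratio", "mean_thickness_mm"),
        baseline_week: float = -30.0,
        pre_week: float = -1.0,
        post_week: float = 30.0,
    ) -> None:
        self.records = records
        self.regions = tuple((b, r) for b, r in regions)
        self.metrics = tuple(metrics)
        self.weeks = (baseline_week, pre_week, post_week)

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs) -> "CartilageTrialModel":
        return cls(records, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CartilageTrialModel":
        return cls(pd.read_csv(path, dtype={"patient_id": str}), **kwargs)

    @classmethod
    def from_alterations(
        cls,
        alterations: pd.DataFrame,
        regions: Sequence[tuple[str, str]] = ANALYZED_REGIONS,
        metrics: Sequence[str] = ("area_ratio", "mean_thickness_mm"),
    ) -> "CartilageTrialResults":
        """Fit directly from a precomputed alteration table (columns
        patient_id, bone, region, metric, before, after)."""
        table = AlterationTable(
            data=alterations.copy(), problems=[], weeks=(-30.0, -1.0, 30.0)
        )
        model = cls.__new__(cls)
        model.records = None
        model.regions = tuple((b, r) for b, r in regions)
        model.metrics = tuple(metrics)
        model.weeks = table.weeks
        return model._fit(table)

    def fit(self) -> "CartilageTrialResults":
        table = compute_alterations(self.records, *self.weeks)
        return self._fit(table)

    def _fit(self, table: AlterationTable) -> "CartilageTrialResults":
        tests, zero_tests, summaries = [], [], []
        for metric in self.metrics:
            for bone, region in self.regions:
                sel = table.data[
                    (table.data.bone == bone)
                    & (table.data.region == region)
                    & (table.data.metric == metric)
                ].sort_values("patient_id")
                if sel.empty:
                    continue
                before = sel["before"].to_numpy()
                after = sel["after"].to_numpy()
                res = wilcoxon_signed_rank(before, after)
                tests.append((bone, region, metric, res))
                for period, col in (("before", before), ("after", after)):
                    zres = wilcoxon_signed_rank(col)
                    zero_tests.append((bone, region, metric, period, zres))
                    summaries.append((bone, region, metric, period, summarize(col)))
        return CartilageTrialResults(
            model=self,
            alterations=table,
            tests=tests,
            zero_tests=zero_tests,
            summaries=summaries,
        )


@dataclass
class CartilageTrialResults:
    """Fitted alteration analysis.

    ``tests`` pairs each (bone, region, metric) with the exact Wilcoxon test
    of before vs after alterations; ``zero_tests`` holds each column's test
    against zero; ``summaries`` the median/IQR/mean of each column.
    """

    model: CartilageTrialModel
    alterations: AlterationTable
    tests: list[tuple[str, str, str, WilcoxonResult]]
    zero_tests: list[tuple[str, str, str, str, WilcoxonResult]]
    summaries: list[tuple[str, str, str, str, SummaryStats]]

    # -- tabular accessors -------------------------------------------------

    @property
    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (b, r, m, res.n_input, res.n_used, res.w_plus, res.w_minus,
                 res.p_one_sided, res.p_two_sided, res.method)
                for b, r, m, res in self.tests
            ],
            columns=["bone", "region", "metric", "n", "n_used", "w_plus", "w_minus",
                     "p_one_sided", "p_two_sided", "method"],
        )

    @property
    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (b, r, m, period, s.median, s.q1, s.q3, s.mean, s.n)
                for b, r, m, period, s in self.summaries
            ],
            columns=["bone", "region", "metric", "period", "median", "q1", "q3", "mean", "n"],
        )

    def p_value(self, bone: str, region: str, metric: str, sided: str = "one_sided") -> float:
        for b, r, m, res in self.tests:
            if (b, r, m) == (bone, region, metric):
                return res.p_one_sided if sided == "one_sided" else res.p_two_sided
        raise KeyError((bone, region, metric))

    # -- report ------------------------------------------------------------

    def summary(self, sided: str = "one_sided") -> str:
        """Wide, human-readable alteration table (the trial-report layout)."""
        out = StringIO()
        cols = [(b, r) for b, r in self.model.regions]
        data = self.alterations.data
        print("Alteration in cartilage quantification before and after treatment", file=out)
        print(f"(before: {self.alterations.weeks[1]:g} w minus {self.alterations.weeks[0]:g} w; "
              f"after: {self.alterations.weeks[2]:g} w minus {self.alterations.weeks[1]:g} w)",
              file=out)
        for metric in self.model.metrics:
            print(f"\n{METRIC_LABELS.get(metric, metric)}", file=out)
            header = ["patient"] + [
                f"{b[:3]}-{r}:{period}" for b, r in cols for period in ("before", "after")
            ]
            print("  " + "  ".join(f"{h:>22}" for h in header), file=out)
            pids = sorted(data[data.metric == metric].patient_id.unique())
            for pid in pids:
                cells = [pid]
                for b, r in cols:
                    sel = data[
                        (data.patient_id == pid) & (data.bone == b)
                        & (data.region == r) & (data.metric == metric)
                    ]
                    for period in ("before", "after"):
                        cells.append(
                            f"{round_half_even(float(sel[period].iloc[0]), 2):.2f}"
                            if len(sel) else "--"
                        )
                print("  " + "  ".join(f"{c:>22}" for c in cells), file=out)
            for stat in ("median", "q1", "q3"):
                cells = [stat]
                for b, r in cols:
                    for period in ("before", "after"):
                        s = self._summary_for(b, r, metric, period)
                        cells.append(f"{round_half_even(getattr(s, stat), 2):.2f}" if s else "--")
                print("  " + "  ".join(f"{c:>22}" for c in cells), file=out)
            cells = ["P value"]
            for b, r in cols:
                try:
                    p = self.p_value(b, r, metric, sided)
                    cells.append(f"{round_half_even(p, 3):.3f}")
                except KeyError:
                    cells.append("--")
                cells.append("")
            print("  " + "  ".join(f"{c:>22}" for c in cells), file=out)
        if self.alterations.problems:
            print("\nPatients with missing timepoints (excluded from tests):", file=out)
            for prob in self.alterations.problems:
                print(f"  {prob}", file=out)
        return out.getvalue()

    def _summary_for(self, bone, region, metric, period) -> Optional[SummaryStats]:
        for b, r, m, per, s in self.summaries:
            if (b, r, m, per) == (bone, region, metric, period):
                return s
        return None
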