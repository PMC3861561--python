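"""Cohort cross-tabulations and per-case reports.

Cross-tabs mirror the layout of published IK distribution tables: one row
per level of a clinicopathological factor, cells holding counts with
row-percentages, plus row totals and a grand total.  Percentages are
recomputed from counts with half-up rounding; counts are authoritative.
Factor level ordering is fixed (e.g. high/moderate/low, GPG/MPG/PPG) so
outputs are diffable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .annotations import FieldAnnotation
from .ik import CaseIK
from .rounding import round_half_up
from .stratify import (
    ClinicalRecord,
    HER2Intensity,
    HER2Continuity,
    HER2Observation,
    HER2Score,
    ReceptorProfile,
    StratificationResult,
)

#: Fixed display order per factor; unlisted factors sort lexically.
LEVEL_ORDERS: dict[str, list] = {
    "ik_class": ["high", "moderate", "low"],
    "er_level": ["high", "low", "negative"],
    "pr_level": ["high", "low", "negative"],
    "npi_group": ["GPG", "MPG", "PPG"],
    "luminal": ["luminal", "non_luminal"],
    "her2_score": [0, 1, 2, 3],
    "grade": [1, 2, 3],
    "node_score": [1, 2, 3],
    "luminal_a_candidate": [True, False],
    "her2_positive": [True, False],
}


@dataclass(frozen=True)
class CrossTab:
    """A counts-with-row-percentages contingency table."""

    row_factor: str
    col_factor: str
    counts: pd.DataFrame  # rows x cols, integer counts
    row_pct: pd.DataFrame  # same shape, half-up 1-decimal row percentages
    row_totals: pd.Series
    grand_total: int

    def formatted(self) -> pd.DataFrame:
        """Cells as ``'pct (count)'`` strings plus a Total column."""
        out = pd.DataFrame(index=self.counts.index, columns=self.counts.columns)
        for r in self.counts.index:
            for c in self.counts.columns:
                out.loc[r, c] = f"{self.row_pct.loc[r, c]:.1f} ({self.counts.loc[r, c]})"
        out["Total"] = self.row_totals
        return out


def stratification_frame(
    results: Sequence[StratificationResult],
) -> pd.DataFrame:
    """Flatten stratification results to a DataFrame (enums as plain values)."""
    rows = []
    for r in results:
        d = r.model_dump()
        d["her2_score"] = int(r.her2_score)
        rows.append(d)
    return pd.DataFrame(rows)


def _ordered_levels(factor: str, values: pd.Series, full: bool = False) -> list:
    """Canonical display order.  With ``full``, every canonical level of a
    known factor appears even if unobserved (published tables print empty
    class columns as ``0.0 (0)``); otherwise only observed levels, ranked."""
    present = list(pd.unique(values))
    order = LEVEL_ORDERS.get(factor)
    if order is None:
        return sorted(present, key=str)
    ranked = list(order) if full else [v for v in order if v in present]
    return ranked + sorted((v for v in present if v not in order), key=str)


def cohort_cross_tab(
    cases: Union[pd.DataFrame, Sequence[StratificationResult]],
    row_factor: str,
    col_factor: str,
) -> CrossTab:
    """Cross-tabulate a stratified cohort by two factors.

    Each cell holds the case count and its percentage of the row total.
    Row totals sum to the grand total by construction.
    """
    df = cases if isinstance(cases, pd.DataFrame) else stratification_frame(list(cases))
    if len(df) == 0:
        raise ValueError("empty cohort")
    for factor in (row_factor, col_factor):
        if factor not in df.columns:
            raise KeyError(f"unknown factor {factor!r}; available: {list(df.columns)}")
    counts = pd.crosstab(df[row_factor], df[col_factor])
    counts = counts.reindex(
        index=_ordered_levels(row_factor, df[row_factor]),
        columns=_ordered_levels(col_factor, df[col_factor], full=True),
        fill_value=0,
    )
    row_totals = counts.sum(axis=1)
    row_pct = counts.apply(
        lambda row: pd.Series(
            [
                round_half_up(100.0 * v / row_totals[row.name], 1)
                if row_totals[row.name]
                else 0.0
                for v in row
            ],
            index=row.index,
        ),
        axis=1,
    )
    return CrossTab(
        row_factor=row_factor,
        col_factor=col_factor,
        counts=counts,
        row_pct=row_pct,
        row_totals=row_totals,
        grand_total=int(row_totals.sum()),
    )


def case_report(
    result: StratificationResult,
    case_ik: CaseIK,
    near_duplicate_pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> dict:
    """Structured per-case report (JSON-serializable).

    Includes every classification field, per-field IKs, the minimum-nuclei
    flag, any near-duplicate marker warnings, and a flag for the
    chemo-stratification-relevant combination (luminal-A candidate with a
    high IK class).
    """
    strat = result.model_dump()
    strat["her2_score"] = int(result.her2_score)
    return {
        "case_id": case_ik.case_id or result.case_id,
        "ik": {
            "per_field_ik": list(case_ik.per_field_ik),
            "per_field_total": list(case_ik.per_field_total),
            "total_nuclei": case_ik.total_nuclei,
            "ik_mean": case_ik.ik_mean,
            "ik_mean_1dp": round_half_up(case_ik.ik_mean, 1),
            "ik_pooled": case_ik.ik_pooled,
            "meets_minimum": case_ik.meets_minimum,
        },
        "stratification": strat,
        "flags": {
            "below_minimum_nuclei": not case_ik.meets_minimum,
            "near_duplicate_pairs": [list(p) for p in (near_duplicate_pairs or [])],
            "luminal_a_high_ik": bool(
                result.luminal_a_candidate and result.ik_class.value == "high"
            ),
        },
    }


# ---------------------------------------------------------------------------
# clinical table I/O
# ---------------------------------------------------------------------------

CLINICAL_REQUIRED = ("case_id", "size_cm", "positive_nodes", "grade", "er_pct", "pr_pct")


def read_clinical_csv(
    path: Path | str,
) -> list[tuple[str, ReceptorProfile, ClinicalRecord]]:
    """Read a case-level clinical table.

    Columns: ``case_id, size_cm, positive_nodes, apical_positive, grade,
    er_pct, pr_pct`` plus either a precomputed ``her2_score`` or the raw
    observation ``her2_pct, her2_intensity, her2_continuity``.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing column(s): {', '.join(missing)}")
    has_score = "her2_score" in df.columns
    has_obs = {"her2_pct", "her2_intensity", "her2_continuity"} <= set(df.columns)
    if not (has_score or has_obs):
        raise ValueError(
            "clinical table needs either her2_score or "
            "her2_pct/her2_intensity/her2_continuity columns"
        )
    out = []
    for _, row in df.iterrows():
        if has_score and not pd.isna(row.get("her2_score")):
            her2: Union[HER2Observation, HER2Score] = HER2Score(int(row["her2_score"]))
        else:
            her2 = HER2Observation(
                pct_cells=float(row["her2_pct"]),
                intensity=HER2Intensity(str(row["her2_intensity"])),
                continuity=HER2Continuity(str(row["her2_continuity"])),
            )
        profile = ReceptorProfile(
            er_pct=float(row["er_pct"]), pr_pct=float(row["pr_pct"]), her2=her2
        )
        clinical = ClinicalRecord(
            size_cm=float(row["size_cm"]),
            positive_nodes=int(row["positive_nodes"]),
            apical_positive=bool(row.get("apical_positive", False)),
            grade=int(row["grade"]),  # type: ignore[arg-type]
        )
        out.append((str(row["case_id"]), profile, clinical))
    return out


def write_clinical_csv(
    cases: Sequence[tuple[str, ReceptorProfile, ClinicalRecord]],
    path: Path | str,
) -> None:
    """Write a clinical table readable by :func:`read_clinical_csv`.

    HER2 is written as the precomputed score when the profile holds one,
    else as the raw observation columns.
    """
    rows = []
    for case_id, profile, clinical in cases:
        row: dict = {
            "case_id": case_id,
            "size_cm": clinical.size_cm,
            "positive_nodes": clinical.positive_nodes,
            "apical_positive": clinical.apical_positive,
            "grade": clinical.grade,
            "er_pct": profile.er_pct,
            "pr_pct": profile.pr_pct,
        }
        if isinstance(profile.her2, HER2Observation):
            row.update(
                her2_pct=profile.her2.pct_cells,
                her2_intensity=profile.her2.intensity.value,
                her2_continuity=profile.her2.continuity.value,
            )
        else:
            row["her2_score"] = int(profile.her2)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
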