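"""Per-field and case-level Ki-67 proliferation index (IK) computation.

The IK of one field is the percentage of Ki-67-positive nuclei among all
tumor nuclei counted in that field.  The case-level IK is the unweighted
arithmetic mean of the per-field IKs — the protocol's primary estimator —
computed over enough fields that at least 1,000 nuclei are counted in
total.  The pooled ratio (total positives over total nuclei) is always
computed alongside as a diagnostic: the two estimators agree exactly when
field totals are equal and diverge otherwise.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .annotations import FieldAnnotation, FieldGeometry
from .errors import EmptyFieldError, MinimumNucleiWarning
from .geometry import field_area_mm2, nuclear_density

#: Recommended minimum number of tumor nuclei per case.
MINIMUM_NUCLEI = 1000


class FieldCounts(BaseModel):
    """Positive/negative nucleus counts for one field."""

    model_config = ConfigDict(frozen=True)

    n_positive: int = Field(ge=0)
    n_negative: int = Field(ge=0)

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative

    @classmethod
    def from_annotation(cls, field: FieldAnnotation) -> "FieldCounts":
        return cls(n_positive=field.n_positive, n_negative=field.n_negative)


class CaseIK(BaseModel):
    """Case-level IK result.

    ``ik_mean`` (mean of per-field IKs) is the primary result; ``ik_pooled``
    is the pooled-count diagnostic.  ``meets_minimum`` records whether the
    total nucleus count reached the recommended minimum.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str
    per_field_ik: tuple[float, ...]
    per_field_total: tuple[int, ...]
    total_nuclei: int
    total_positive: int
    ik_mean: float
    ik_pooled: float
    meets_minimum: bool
    per_field_density: tuple[float, ...] = ()

    @property
    def n_fields(self) -> int:
        return len(self.per_field_ik)


def per_field_ik(counts: FieldCounts) -> float:
    """IK of one field: ``100 * positives / total`` (percent)."""
    total = counts.n_total
    if total < 1:
        raise EmptyFieldError("empty field: at least one counted nucleus is required")
    return 100.0 * counts.n_positive / total


def aggregate_case(
    fields: Sequence[FieldCounts],
    minimum: int = MINIMUM_NUCLEI,
    case_id: str = "",
    geometry: Optional[FieldGeometry] = None,
) -> CaseIK:
    """Aggregate per-field counts into a case-level IK.

    Emits a :class:`MinimumNucleiWarning` (not an error) when the total is
    below ``minimum``, so partial cases remain inspectable.  Field order
    does not affect any result.
    """
    if len(fields) == 0:
        raise EmptyFieldError("at least one field is required")
    iks = tuple(per_field_ik(c) for c in fields)
    totals = tuple(c.n_total for c in fields)
    total = sum(totals)
    positives = sum(c.n_positive for c in fields)
    meets = total >= minimum
    if not meets:
        warnings.warn(
            f"case {case_id or '<unnamed>'}: only {total} nuclei counted, "
            f"below the recommended minimum of {minimum}",
            MinimumNucleiWarning,
            stacklevel=2,
        )
    densities: tuple[float, ...] = ()
    if geometry is not None:
        area = field_area_mm2(geometry)
        densities = tuple(nuclear_density(t, area) for t in totals)
    return CaseIK(
        case_id=case_id,
        per_field_ik=iks,
        per_field_total=totals,
        total_nuclei=total,
        total_positive=positives,
        ik_mean=float(np.mean(iks)),
        ik_pooled=100.0 * positives / total,
        meets_minimum=meets,
        per_field_density=densities,
    )


def aggregate_annotations(
    fields: Sequence[FieldAnnotation],
    minimum: int = MINIMUM_NUCLEI,
) -> CaseIK:
    """Aggregate a case's :class:`FieldAnnotation` set (convenience wrapper)."""
    if len(fields) == 0:
        raise EmptyFieldError("at least one field is required")
    case_ids = {f.case_id for f in fields}
    if len(case_ids) > 1:
        raise ValueError(f"fields span multiple cases: {sorted(case_ids)}")
    return aggregate_case(
        [FieldCounts.from_annotation(f) for f in fields],
        minimum=minimum,
        case_id=next(iter(case_ids)),
        geometry=fields[0].geometry,
    )


def images_needed(nuclei_per_image: int, minimum: int = MINIMUM_NUCLEI) -> int:
    """Fields required to reach ``minimum`` nuclei at a given per-field yield.

    ``ceil(minimum / nuclei_per_image)``: e.g. 7 fields at the typical median
    of 151 nuclei/field, but only 2 for dense tumors exceeding 500
    nuclei/field.
    """
    if nuclei_per_image < 1:
        raise ValueError("nuclei_per_image must be at least 1")
    return math.ceil(minimum / nuclei_per_image)


def summarize_cohort_counts(
    fields: Sequence[FieldCounts],
    geometry: FieldGeometry,
) -> pd.DataFrame:
    """Order statistics of per-field totals, positives, and densities.

    All fields are pooled across cases.  Returns a DataFrame indexed by
    ``mean/median/min/max`` with columns ``total``, ``positive``,
    ``density_per_mm2`` (full precision; round for presentation).  The
    median of an even number of fields is the mean of the central pair.
    """
    if len(fields) == 0:
        raise EmptyFieldError("at least one field is required")
    totals = np.array([c.n_total for c in fields], dtype=float)
    positives = np.array([c.n_positive for c in fields], dtype=float)
    area = field_area_mm2(geometry)
    densities = np.array([nuclear_density(int(t), area) for t in totals])
    stats = {
        "mean": np.mean,
        "median": np.median,
        "min": np.min,
        "max": np.max,
    }
    return pd.DataFrame(
        {
            "total": {k: f(totals) for k, f in stats.items()},
            "positive": {k: f(positives) for k, f in stats.items()},
            "density_per_mm2": {k: f(densities) for k, f in stats.items()},
        }
    )


def case_ik_frame(cases: Sequence[CaseIK]) -> pd.DataFrame:
    """Tabulate case results for CSV/JSON export."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "n_fields": [c.n_fields for c in cases],
            "total_nuclei": [c.total_nuclei for c in cases],
            "ik_mean": [c.ik_mean for c in cases],
            "ik_pooled": [c.ik_pooled for c in cases],
            "meets_minimum": [c.meets_minimum for c in cases],
        }
    )
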