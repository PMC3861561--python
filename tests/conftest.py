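import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ki67kit import (
    PAPER_FIELD,
    ClinicalRecord,
    FieldAnnotation,
    FieldGeometry,
    HER2Score,
    PointMarker,
    ReceptorProfile,
    classify_case,
)


@pytest.fixture
def geometry() -> FieldGeometry:
    return PAPER_FIELD


@pytest.fixture
def calibrated_geometry() -> FieldGeometry:
    """Geometry with a pixel scale, for px-unit round trips."""
    return FieldGeometry(width_um=310.3, height_um=232.72, um_per_px=0.12121)


@pytest.fixture
def small_field(geometry) -> FieldAnnotation:
    """Three markers: two positive, one negative, all in-bounds."""
    return FieldAnnotation(
        field_id="f1",
        case_id="c1",
        geometry=geometry,
        markers=(
            PointMarker(x=10.0, y=20.0, label="positive"),
            PointMarker(x=100.5, y=50.25, label="positive"),
            PointMarker(x=300.0, y=200.0, label="negative"),
        ),
    )


# level -> representative percentage / IK used to synthesize cohort cases
_RECEPTOR_PCT = {"high": 60.0, "low": 30.0}
_IK_PCT = {"high": 40.0, "moderate": 25.0, "low": 10.0}

#: Published joint distribution of 55 ER+/PR+/HER2- luminal tumors over
#: combined ER/PR expression levels and IK class:
#: (er_level, pr_level) -> counts for (high, moderate, low) IK.
TABLE_V_COUNTS = {
    ("high", "high"): (3, 14, 6),
    ("high", "low"): (3, 3, 11),
    ("low", "high"): (3, 0, 6),
    ("low", "low"): (3, 3, 0),
}


def build_luminal_a_cohort():
    """Synthesize the 55-case luminal-A cohort matching the published
    ER/PR-level x IK-class joint counts, via classify_case."""
    results = []
    i = 0
    for (er_level, pr_level), counts in TABLE_V_COUNTS.items():
        for ik_name, n in zip(("high", "moderate", "low"), counts):
            for _ in range(n):
                i += 1
                profile = ReceptorProfile(
                    er_pct=_RECEPTOR_PCT[er_level],
                    pr_pct=_RECEPTOR_PCT[pr_level],
                    her2=HER2Score.one,
                )
                clinical = ClinicalRecord(size_cm=2.0, positive_nodes=0, grade=2)
                results.append(
                    classify_case(
                        _IK_PCT[ik_name], profile, clinical, case_id=f"lumA-{i:02d}"
                    )
                )
    return results


@pytest.fixture(scope="session")
def luminal_a_cohort():
    return build_luminal_a_cohort()
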