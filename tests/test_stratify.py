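"""Receptor levels, HER2 scoring, luminal typing, IK classes, and NPI."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ki67kit import (
    ClinicalRecord,
    HER2Observation,
    HER2Score,
    HER2UnscorableError,
    IKClass,
    LuminalStatus,
    NPIGroup,
    ReceptorLevel,
    ReceptorProfile,
    classify_case,
    her2_positive,
    her2_score,
    ik_class,
    luminal_class,
    node_score,
    npi_group,
    npi_value,
    receptor_level,
    sbr_grade,
)

# -- receptor levels --------------------------------------------------------


@pytest.mark.parametrize(
    "pct,expected",
    [
        (0.5, ReceptorLevel.negative),
        (1.0, ReceptorLevel.negative),  # positivity is strictly >1%
        (1.01, ReceptorLevel.low),
        (30.0, ReceptorLevel.low),
        (50.0, ReceptorLevel.low),  # high is strictly >50%
        (60.0, ReceptorLevel.high),
        (100.0, ReceptorLevel.high),
    ],
)
def test_receptor_levels(pct, expected):
    assert receptor_level(pct) is expected


def test_receptor_out_of_range():
    with pytest.raises(ValueError):
        receptor_level(101.0)


# -- HER2 -------------------------------------------------------------------


@pytest.mark.parametrize(
    "pct,intensity,continuity,expected",
    [
        (35, "intense", "continuous", HER2Score.three),
        (25, "intense", "continuous", HER2Score.two),
        (30, "intense", "continuous", HER2Score.two),  # 3+ requires strictly >30%
        (5, "intense", "continuous", HER2Score.zero),  # <10% is always 0
        (15, "weak", "discontinuous", HER2Score.one),
        (15, "weak", "continuous", HER2Score.two),
        (15, "moderate", "continuous", HER2Score.two),
        (0, "absent", "discontinuous", HER2Score.zero),
        (90, "absent", "continuous", HER2Score.zero),
    ],
)
def test_her2_scores(pct, intensity, continuity, expected):
    obs = HER2Observation(pct_cells=pct, intensity=intensity, continuity=continuity)
    assert her2_score(obs) is expected


def test_her2_positivity_is_strictly_3plus():
    assert her2_positive(HER2Score.three)
    assert not her2_positive(HER2Score.two)


@pytest.mark.parametrize(
    "pct,intensity,continuity",
    [
        (10, "weak", "discontinuous"),  # exactly 10% is covered by no rule
        (20, "moderate", "discontinuous"),
        (20, "intense", "discontinuous"),
    ],
)
def test_her2_gaps_raise_not_default(pct, intensity, continuity):
    obs = HER2Observation(pct_cells=pct, intensity=intensity, continuity=continuity)
    with pytest.raises(HER2UnscorableError):
        her2_score(obs)


@given(
    pct=st.floats(min_value=0, max_value=100, allow_nan=False),
    intensity=st.sampled_from(["absent", "weak", "moderate", "intense"]),
    continuity=st.sampled_from(["discontinuous", "continuous"]),
)
def test_her2_total_over_printed_domain(pct, intensity, continuity):
    """Every observation either gets exactly one printed score or an
    explicit unscorable error; the covered combinations never error."""
    obs = HER2Observation(pct_cells=pct, intensity=intensity, continuity=continuity)
    covered = (
        intensity == "absent"
        or pct < 10
        or (
            pct > 10
            and (
                (intensity == "weak")  # discontinuous->1+, continuous->2+
                or (intensity == "moderate" and continuity == "continuous")
            )
        )
        or (intensity == "intense" and continuity == "continuous")
    )
    if covered:
        assert her2_score(obs) in list(HER2Score)
    else:
        with pytest.raises(HER2UnscorableError):
            her2_score(obs)


# -- IK classes -------------------------------------------------------------


@pytest.mark.parametrize(
    "ik,expected",
    [
        (0.0, IKClass.low),
        (12.6, IKClass.low),
        (15.0, IKClass.low),
        (15.5, IKClass.moderate),  # the (15,16) gap belongs to moderate
        (30.0, IKClass.moderate),
        (30.1, IKClass.high),
        (59.6, IKClass.high),
        (100.0, IKClass.high),
    ],
)
def test_ik_class_bands(ik, expected):
    assert ik_class(ik) is expected


def test_ik_class_luminal_b_scheme():
    assert ik_class(14.5, scheme="luminalB14") is IKClass.high
    assert ik_class(14.0, scheme="luminalB14") is IKClass.low


@given(ik=st.floats(min_value=0, max_value=100, allow_nan=False))
def test_ik_classes_partition_the_range(ik):
    cls = ik_class(ik)
    expected = (
        IKClass.low if ik <= 15 else IKClass.moderate if ik <= 30 else IKClass.high
    )
    assert cls is expected


def test_ik_class_rejects_out_of_range():
    with pytest.raises(ValueError):
        ik_class(-0.1)
    with pytest.raises(ValueError):
        ik_class(100.5)


# -- luminal typing ---------------------------------------------------------


@pytest.mark.parametrize(
    "er,pr,her2,status,candidate",
    [
        (40, 20, HER2Score.one, LuminalStatus.luminal, True),
        (0, 0, HER2Score.three, LuminalStatus.non_luminal, False),
        (0, 30, HER2Score.three, LuminalStatus.luminal, False),  # "and/or" rule
        (60, 0.5, HER2Score.zero, LuminalStatus.luminal, False),  # PR negative
        (60, 60, HER2Score.three, LuminalStatus.luminal, False),  # HER2+ blocks A
    ],
)
def test_luminal_class(er, pr, her2, status, candidate):
    got_status, got_candidate = luminal_class(
        ReceptorProfile(er_pct=er, pr_pct=pr, her2=her2)
    )
    assert got_status is status
    assert got_candidate is candidate


def test_profile_scores_raw_her2_observation():
    profile = ReceptorProfile(
        er_pct=40,
        pr_pct=40,
        her2=HER2Observation(pct_cells=50, intensity="intense", continuity="continuous"),
    )
    assert profile.her2_score() is HER2Score.three
    _, candidate = luminal_class(profile)
    assert not candidate


# -- nodes and NPI ----------------------------------------------------------


@pytest.mark.parametrize(
    "nodes,apical,expected",
    [(0, False, 1), (1, False, 2), (3, False, 2), (4, False, 3), (1, True, 3), (0, True, 3)],
)
def test_node_score(nodes, apical, expected):
    assert node_score(nodes, apical) == expected


@pytest.mark.parametrize(
    "size,nodes,grade,expected",
    [(2.0, 1, 1, 2.4), (2.8, 2, 3, 5.56), (5.0, 3, 3, 7.0)],
)
def test_npi_value(size, nodes, grade, expected):
    assert npi_value(size, nodes, grade) == pytest.approx(expected)


@pytest.mark.parametrize(
    "npi,expected",
    [
        (2.4, NPIGroup.GPG),
        (3.4, NPIGroup.MPG),  # moderate band closed on both ends
        (5.4, NPIGroup.MPG),
        (5.56, NPIGroup.PPG),
    ],
)
def test_npi_groups(npi, expected):
    assert npi_group(npi) is expected


@given(
    size=st.floats(min_value=0.1, max_value=15, allow_nan=False),
    ns=st.integers(min_value=1, max_value=3),
    grade=st.integers(min_value=1, max_value=3),
)
def test_npi_group_monotone_in_each_argument(size, ns, grade):
    """Larger size, node score or grade never improves the prognostic group."""
    order = [NPIGroup.GPG, NPIGroup.MPG, NPIGroup.PPG]
    base = order.index(npi_group(npi_value(size, ns, grade)))
    assert order.index(npi_group(npi_value(size + 1.0, ns, grade))) >= base
    if ns < 3:
        assert order.index(npi_group(npi_value(size, ns + 1, grade))) >= base
    if grade < 3:
        assert order.index(npi_group(npi_value(size, ns, grade + 1))) >= base


@pytest.mark.parametrize("score,grade", [(3, 1), (5, 1), (6, 2), (7, 2), (8, 3), (9, 3)])
def test_sbr_grade_mapping(score, grade):
    assert sbr_grade(score) == grade


# -- composition ------------------------------------------------------------


def test_classify_case_moderate_luminal_mpg():
    """IK 21.7, ER 60, PR 60, HER2 1+, node-negative, grade 2, 2 cm:
    moderate IK, luminal-A candidate, NPI 3.4 -> MPG."""
    result = classify_case(
        21.7,
        ReceptorProfile(er_pct=60, pr_pct=60, her2=HER2Score.one),
        ClinicalRecord(size_cm=2.0, positive_nodes=0, grade=2),
    )
    assert result.ik_class is IKClass.moderate
    assert result.luminal is LuminalStatus.luminal
    assert result.luminal_a_candidate
    assert result.npi == pytest.approx(3.4)
    assert result.npi_group is NPIGroup.MPG


def test_classify_case_high_non_luminal():
    result = classify_case(
        59.6,
        ReceptorProfile(er_pct=0, pr_pct=0, her2=HER2Score.zero),
        ClinicalRecord(size_cm=2.8, positive_nodes=5, grade=3),
    )
    assert result.ik_class is IKClass.high
    assert result.luminal is LuminalStatus.non_luminal
    assert not result.luminal_a_candidate


def test_classify_case_floor():
    result = classify_case(
        0.0,
        ReceptorProfile(er_pct=0, pr_pct=0, her2=HER2Score.zero),
        ClinicalRecord(size_cm=1.0, positive_nodes=0, grade=1),
    )
    assert result.ik_class is IKClass.low
    assert result.luminal is LuminalStatus.non_luminal
    assert result.npi_group is NPIGroup.GPG
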