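"""Clinicopathological stratification of breast carcinoma cases.

Composes the rule set used alongside the IK measurement:

* ER/PR levels — positive above 1%; positive cases split into low (≤50%)
  and high (>50%) expression.
* HER2 score — the 0/1+/2+/3+ membrane-staining rules; only 3+ counts as
  HER2-positive.  Observations outside the printed rule combinations raise
  :class:`~ki67kit.errors.HER2UnscorableError` rather than defaulting.
* Luminal typing — luminal if ER and/or PR positive; the luminal-A
  candidate flag marks ER+/PR+/HER2− cases, the subgroup whose therapy
  decisions hinge on the IK.
* IK classes — the St. Gallen 2009 bands low ≤15 < moderate ≤30 < high
  (half-open bands anchored at the printed edges, since the printed
  "≤15 / 16–30 / >30" leaves (15,16) undefined for continuous IK), plus an
  alternative binary 14% luminal-A/B threshold.
* Nottingham Prognostic Index — 0.2 x size(cm) + node score (1–3) +
  grade (1–3), banded GPG < 3.4 ≤ MPG ≤ 5.4 < PPG.
"""

from __future__ import annotations

from enum import Enum, IntEnum
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from .errors import HER2UnscorableError
from .ik import CaseIK


class ReceptorLevel(str, Enum):
    negative = "negative"
    low = "low"
    high = "high"


class HER2Intensity(str, Enum):
    absent = "absent"
    weak = "weak"
    moderate = "moderate"
    intense = "intense"


class HER2Continuity(str, Enum):
    discontinuous = "discontinuous"
    continuous = "continuous"


class IKClass(str, Enum):
    low = "low"
    moderate = "moderate"
    high = "high"


class LuminalStatus(str, Enum):
    luminal = "luminal"
    non_luminal = "non_luminal"


class NPIGroup(str, Enum):
    GPG = "GPG"  # good prognostic group
    MPG = "MPG"  # moderate prognostic group
    PPG = "PPG"  # poor prognostic group


class HER2Score(IntEnum):
    zero = 0
    one = 1
    two = 2
    three = 3


class HER2Observation(BaseModel):
    """Raw HER2 membrane-staining observation."""

    model_config = ConfigDict(frozen=True)

    pct_cells: float = Field(ge=0, le=100)
    intensity: HER2Intensity
    continuity: HER2Continuity


class ReceptorProfile(BaseModel):
    """ER/PR percentages plus a HER2 observation or precomputed score.

    HER2 may be given as a raw observation (scored by the rule engine) or
    as a precomputed 0–3 score for cohorts scored elsewhere.
    """

    model_config = ConfigDict(frozen=True)

    er_pct: float = Field(ge=0, le=100)
    pr_pct: float = Field(ge=0, le=100)
    her2: Union[HER2Observation, HER2Score]

    def her2_score(self) -> HER2Score:
        if isinstance(self.her2, HER2Observation):
            return her2_score(self.her2)
        return self.her2


class ClinicalRecord(BaseModel):
    """Morphological inputs to the NPI; grade is consumed, not derived."""

    model_config = ConfigDict(frozen=True)

    size_cm: float = Field(gt=0)
    positive_nodes: int = Field(ge=0)
    apical_positive: bool = False
    grade: Literal[1, 2, 3]
    age_group: Optional[Literal["pre", "post"]] = None
    stage: Optional[Literal["I", "II", "III"]] = None


class StratificationResult(BaseModel):
    """Full classification of one case."""

    model_config = ConfigDict(frozen=True)

    case_id: str = ""
    ik_class: IKClass
    luminal: LuminalStatus
    luminal_a_candidate: bool
    er_level: ReceptorLevel
    pr_level: ReceptorLevel
    her2_score: HER2Score
    her2_positive: bool
    node_score: Literal[1, 2, 3]
    npi: float
    npi_group: NPIGroup


# ---------------------------------------------------------------------------
# component rules
# ---------------------------------------------------------------------------

#: Receptor positivity threshold (percent): strictly above is positive.
RECEPTOR_POSITIVE_PCT = 1.0
#: Split between low and high receptor expression (percent).
RECEPTOR_HIGH_PCT = 50.0


def receptor_level(pct: float) -> ReceptorLevel:
    """ER/PR level: negative ≤1% < low ≤50% < high."""
    if not 0 <= pct <= 100:
        raise ValueError(f"receptor percentage {pct} outside [0, 100]")
    if pct <= RECEPTOR_POSITIVE_PCT:
        return ReceptorLevel.negative
    if pct <= RECEPTOR_HIGH_PCT:
        return ReceptorLevel.low
    return ReceptorLevel.high


def her2_score(obs: HER2Observation) -> HER2Score:
    """Score a HER2 observation 0/1+/2+/3+.

    Rules: 0 — reaction absent or in <10% of cells; 1+ — weak and
    discontinuous in >10%; 2+ — weak/moderate and continuous in >10%, or
    intense and continuous in ≤30%; 3+ — intense and continuous in >30%.
    Only 3+ is HER2-positive.  Combinations the rules do not cover (e.g.
    exactly 10%, or moderate/intense discontinuous staining) raise
    :class:`HER2UnscorableError` — never a silent default.
    """
    if obs.intensity is HER2Intensity.absent or obs.pct_cells < 10:
        return HER2Score.zero
    inten, cont, pct = obs.intensity, obs.continuity, obs.pct_cells
    if inten is HER2Intensity.weak and cont is HER2Continuity.discontinuous:
        if pct > 10:
            return HER2Score.one
    elif cont is HER2Continuity.continuous:
        if inten in (HER2Intensity.weak, HER2Intensity.moderate):
            if pct > 10:
                return HER2Score.two
        elif inten is HER2Intensity.intense:
            return HER2Score.three if pct > 30 else HER2Score.two
    raise HER2UnscorableError(
        f"HER2 observation ({pct}% cells, {inten.value}, {cont.value}) is not "
        "covered by the 0/1+/2+/3+ scoring rules; review manually"
    )


def her2_positive(score: HER2Score) -> bool:
    """Positivity is strictly score 3+ (2+ remains 'questionable')."""
    return score == HER2Score.three


#: St. Gallen 2009 IK band edges (percent).
IK_LOW_MAX = 15.0
IK_MODERATE_MAX = 30.0
#: Alternative luminal-A/B threshold (percent).
IK_LUMINAL_B_THRESHOLD = 14.0

IKScheme = Literal["stgallen2009", "luminalB14"]


def ik_class(ik: float, scheme: IKScheme = "stgallen2009") -> IKClass:
    """Classify an IK percentage.

    ``stgallen2009``: low ≤15 < moderate ≤30 < high.  ``luminalB14``: binary
    — ``high`` for IK >14 (the luminal-B side), ``low`` otherwise.
    """
    if not 0 <= ik <= 100:
        raise ValueError(f"IK {ik} outside [0, 100]")
    if scheme == "luminalB14":
        return IKClass.high if ik > IK_LUMINAL_B_THRESHOLD else IKClass.low
    if scheme != "stgallen2009":
        raise ValueError(f"unknown IK scheme {scheme!r}")
    if ik <= IK_LOW_MAX:
        return IKClass.low
    if ik <= IK_MODERATE_MAX:
        return IKClass.moderate
    return IKClass.high


def luminal_class(profile: ReceptorProfile) -> tuple[LuminalStatus, bool]:
    """Luminal typing and luminal-A candidacy.

    Luminal: ER and/or PR positive (each >1%), irrespective of HER2.
    Luminal-A candidate: ER+ and PR+ and HER2 not 3+.
    """
    er_pos = receptor_level(profile.er_pct) is not ReceptorLevel.negative
    pr_pos = receptor_level(profile.pr_pct) is not ReceptorLevel.negative
    status = LuminalStatus.luminal if (er_pos or pr_pos) else LuminalStatus.non_luminal
    candidate = er_pos and pr_pos and not her2_positive(profile.her2_score())
    return status, candidate


def node_score(positive_nodes: int, apical_positive: bool = False) -> int:
    """Lymph node score: 1 — none; 2 — 1–3 positive; 3 — ≥4 or apical positive."""
    if positive_nodes < 0:
        raise ValueError("positive_nodes must be non-negative")
    if apical_positive or positive_nodes >= 4:
        return 3
    if positive_nodes >= 1:
        return 2
    return 1


def npi_value(size_cm: float, node_score: int, grade: int) -> float:
    """NPI = 0.2 x tumor size (cm) + node score (1–3) + grade (1–3)."""
    if size_cm <= 0:
        raise ValueError("size_cm must be positive")
    if node_score not in (1, 2, 3):
        raise ValueError("node_score must be 1, 2 or 3")
    if grade not in (1, 2, 3):
        raise ValueError("grade must be 1, 2 or 3")
    return size_cm * 0.2 + node_score + grade


#: NPI prognostic band edges; the moderate band is closed on both ends.
NPI_GPG_MAX = 3.4
NPI_MPG_MAX = 5.4


def npi_group(npi: float) -> NPIGroup:
    """NPI prognostic group: GPG < 3.4 ≤ MPG ≤ 5.4 < PPG."""
    if npi < NPI_GPG_MAX:
        return NPIGroup.GPG
    if npi <= NPI_MPG_MAX:
        return NPIGroup.MPG
    return NPIGroup.PPG


def sbr_grade(sbr_score: int) -> int:
    """Elston–Ellis grade from a total SBR score: 3–5 → 1, 6–7 → 2, 8–9 → 3.

    Provided as a convenience; grade may always be supplied directly.
    """
    if not 3 <= sbr_score <= 9:
        raise ValueError("SBR total score must be between 3 and 9")
    if sbr_score <= 5:
        return 1
    if sbr_score <= 7:
        return 2
    return 3


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def classify_case(
    case_ik: Union[CaseIK, float],
    profile: ReceptorProfile,
    clinical: ClinicalRecord,
    scheme: IKScheme = "stgallen2009",
    case_id: str = "",
) -> StratificationResult:
    """Apply every stratification rule to one case (deterministic).

    ``case_ik`` may be a :class:`CaseIK` (its ``ik_mean`` is used) or a bare
    IK percentage.
    """
    if isinstance(case_ik, CaseIK):
        ik = case_ik.ik_mean
        case_id = case_id or case_ik.case_id
    else:
        ik = float(case_ik)
    score = profile.her2_score()
    status, candidate = luminal_class(profile)
    ns = node_score(clinical.positive_nodes, clinical.apical_positive)
    npi = npi_value(clinical.size_cm, ns, clinical.grade)
    return StratificationResult(
        case_id=case_id,
        ik_class=ik_class(ik, scheme),
        luminal=status,
        luminal_a_candidate=candidate,
        er_level=receptor_level(profile.er_pct),
        pr_level=receptor_level(profile.pr_pct),
        her2_score=score,
        her2_positive=her2_positive(score),
        node_score=ns,
        npi=npi,
        npi_group=npi_group(npi),
    )
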