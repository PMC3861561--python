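"""Full clinicopathological stratification of one case.

Combines a measured IK with receptor and morphological inputs: ER/PR
levels, HER2 score, luminal typing, St. Gallen IK class, and the
Nottingham Prognostic Index.
"""

import json

from ki67kit import (
    ClinicalRecord,
    HER2Observation,
    ReceptorProfile,
    classify_case,
)

profile = ReceptorProfile(
    er_pct=60.0,
    pr_pct=35.0,
    her2=HER2Observation(pct_cells=20, intensity="intense", continuity="continuous"),
)
clinical = ClinicalRecord(size_cm=2.8, positive_nodes=2, apical_positive=False, grade=2)

result = classify_case(21.7, profile, clinical)
print(json.dumps({k: v for k, v in result.model_dump().items() if k != "case_id"},
                 indent=1, default=str))
# IK 21.7% falls in the moderate band (15 < IK <= 30).  ER 60% is high, PR
# 35% low; HER2 staining that is intense+continuous in only 20% of cells
# scores 2+ ("questionable"), so the case is not HER2-positive and remains
# a luminal-A candidate (ER+/PR+/HER2-).  NPI = 0.2*2.8 + 2 + 2 = 4.56,
# the moderate prognostic group.
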