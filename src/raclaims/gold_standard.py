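"""Clinical effectiveness gold standard from registry visits.

Disease activity is summarized with the 4-variable DAS28-ESR

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*GH

(TJC28/SJC28 tender/swollen 28-joint counts, ESR in mm/h floored at 1,
GH the patient global on 0-100) and with the Clinical Disease Activity
Index

    CDAI = TJC28 + SJC28 + PtGA/10 + PhGA/10

(globals recorded on 0-100, CDAI defined on 0-10 component scales, so the
index ranges 0-76).

Under the primary definition an episode is clinically effective when the
patient reaches low disease activity (DAS28 <= 3.2) or improves by more
than 1.2 DAS28 units from baseline, *and* is highly adherent to the index
drug.  Two LDA-only variants support sensitivity analyses without a
baseline visit: DAS28 <= 3.2 alone, or CDAI < 11 alone, each still with
the adherence requirement.
"""

from __future__ import annotations

import enum
import math

from .adherence import AdherenceResult
from .data_model import GoldStandardResult, RegistryVisit, TreatmentEpisode

DAS28_LDA_THRESHOLD = 3.2
DAS28_IMPROVEMENT_THRESHOLD = 1.2
CDAI_LDA_THRESHOLD = 11.0


class GoldStandardMode(str, enum.Enum):
    PRIMARY_DAS28 = "primary_das28"
    LDA_ONLY_DAS28 = "lda_only_das28"
    LDA_ONLY_CDAI = "lda_only_cdai"


def das28_esr(
    tjc28: float, sjc28: float, esr_mm_hr: float, patient_global: float
) -> float:
    """4-variable DAS28 with ESR; patient global on a 0-100 scale.

    ESR is floored at 1 mm/h so the logarithm stays defined; with all
    inputs at their floor the score is exactly 0.
    """
    if min(tjc28, sjc28, esr_mm_hr, patient_global) < 0:
        raise ValueError("DAS28 inputs must be non-negative")
    esr = max(esr_mm_hr, 1.0)
    return (
        0.56 * math.sqrt(tjc28)
        + 0.28 * math.sqrt(sjc28)
        + 0.70 * math.log(esr)
        + 0.014 * patient_global
    )


def cdai(
    tjc28: float, sjc28: float, patient_global: float, physician_global: float
) -> float:
    """CDAI from 28-joint counts and 0-100 globals (rescaled to 0-10)."""
    if not (0 <= tjc28 <= 28 and 0 <= sjc28 <= 28):
        raise ValueError("joint counts must be in [0, 28]")
    if not (0 <= patient_global <= 100 and 0 <= physician_global <= 100):
        raise ValueError("globals must be in [0, 100]")
    return tjc28 + sjc28 + patient_global / 10.0 + physician_global / 10.0


def das28_of_visit(visit: RegistryVisit) -> float:
    return das28_esr(visit.tjc28, visit.sjc28, visit.esr_mm_hr, visit.patient_global)


def cdai_of_visit(visit: RegistryVisit) -> float:
    return cdai(visit.tjc28, visit.sjc28, visit.patient_global, visit.physician_global)


def evaluate_gold_standard(
    episode: TreatmentEpisode,
    adherence: AdherenceResult,
    mode: GoldStandardMode = GoldStandardMode.PRIMARY_DAS28,
    improvement_strict: bool = True,
) -> GoldStandardResult:
    """Classify an episode against the clinical gold standard.

    The primary mode requires a baseline visit (for the improvement
    criterion); the LDA-only modes use the outcome visit alone.
    ``improvement_strict`` controls whether improvement must strictly
    exceed 1.2 units (the default) or may equal it.
    """
    outcome = episode.outcome_visit
    das_out = das28_of_visit(outcome)
    das_base: float | None = None
    reached_lda = das_out <= DAS28_LDA_THRESHOLD
    improved = False

    if mode == GoldStandardMode.PRIMARY_DAS28:
        if episode.baseline_visit is None:
            raise ValueError(
                "primary gold standard requires a baseline visit for "
                f"patient {episode.patient_id}"
            )
        das_base = das28_of_visit(episode.baseline_visit)
        delta = das_base - das_out
        improved = (
            delta > DAS28_IMPROVEMENT_THRESHOLD
            if improvement_strict
            else delta >= DAS28_IMPROVEMENT_THRESHOLD
        )
        clinical = reached_lda or improved
    elif mode == GoldStandardMode.LDA_ONLY_DAS28:
        clinical = reached_lda
    elif mode == GoldStandardMode.LDA_ONLY_CDAI:
        clinical = cdai_of_visit(outcome) < CDAI_LDA_THRESHOLD
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown mode {mode!r}")

    return GoldStandardResult(
        episode=episode,
        effective=clinical and adherence.adherent,
        das28_outcome=das_out,
        das28_baseline=das_base,
        reached_lda=reached_lda,
        improved_gt_1_2=improved,
        adherent=adherence.adherent,
    )
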