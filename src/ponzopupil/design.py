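"""Experimental design construction and AQ questionnaire scoring.

The session design fully crosses 5 figurine sizes with 2 apparent
locations (near / far end of an illusory corridor), 10 repetitions per
cell, split into two balanced blocks of 50 trials.  The AQ
(Autism-Spectrum Quotient) is a 50-item self-report questionnaire on a
4-point agreement scale, binary-scored and summed to 0-50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIZE_DELTAS",
    "LOCATIONS",
    "RESPONSE_LEVELS",
    "AQ_CLINICAL_CUTOFF",
    "StimulusSet",
    "TrialCondition",
    "AQScore",
    "stimulus_heights",
    "build_trial_list",
    "score_aq",
    "trial_list_to_frame",
    "load_aq_responses",
    "load_scoring_key",
]

#: Proportional height offsets of the five figurines relative to the base.
SIZE_DELTAS: tuple[float, ...] = (-0.20, -0.10, 0.0, 0.10, 0.20)

#: Apparent 3D locations of the figurine within the corridor.
LOCATIONS: tuple[str, str] = ("near", "far")

#: Admissible AQ item responses (4-point agreement scale).
RESPONSE_LEVELS: tuple[str, ...] = (
    "strongly_agree",
    "slightly_agree",
    "slightly_disagree",
    "strongly_disagree",
)

#: AQ score at or above which a clinical assessment is recommended.
AQ_CLINICAL_CUTOFF: int = 32

N_AQ_ITEMS: int = 50
N_SIZE_LEVELS: int = 5
N_REPETITIONS: int = 10
N_BLOCKS: int = 2
TRIALS_PER_BLOCK: int = 50


@dataclass(frozen=True)
class StimulusSet:
    """Geometry and photometry of the five figurine stimuli.

    Heights are derived multiplicatively: ``base_height_deg * (1 + delta)``
    for each entry of ``size_deltas``.
    """

    base_height_deg: float = 7.8
    size_deltas: tuple[float, ...] = SIZE_DELTAS
    luminance_figurine_cd_m2: float = 55.0
    luminance_green_cd_m2: float = 1.7
    luminance_red_cd_m2: float = 2.0

    def __post_init__(self) -> None:
        if self.base_height_deg <= 0:
            raise ValueError("base_height_deg must be positive")
        if len(self.size_deltas) != 5:
            raise ValueError("exactly 5 size offsets are required")
        if not np.all(np.diff(self.size_deltas) > 0):
            raise ValueError("size offsets must be strictly increasing")

    @property
    def heights_deg(self) -> np.ndarray:
        """Figurine heights in degrees of visual angle, smallest first."""
        return self.base_height_deg * (1.0 + np.asarray(self.size_deltas))

    def height_for_level(self, size_level: int) -> float:
        """Height of the figurine at ``size_level`` (1 = smallest)."""
        if not 1 <= size_level <= len(self.size_deltas):
            raise ValueError(f"size_level out of range: {size_level}")
        return float(self.heights_deg[size_level - 1])


def stimulus_heights(stimulus_set: StimulusSet | None = None) -> np.ndarray:
    """Return the five figurine heights (degrees), strictly increasing."""
    if stimulus_set is None:
        stimulus_set = StimulusSet()
    return stimulus_set.heights_deg


@dataclass(frozen=True)
class TrialCondition:
    """Condition labels of a single trial."""

    size_level: int  # 1..5, smallest to largest
    location: str  # 'near' or 'far'
    repetition: int  # 1..10 within the (size, location) cell
    block: int  # 1 or 2
    trial_index_in_block: int  # 1..50

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location: {self.location!r}")


def build_trial_list(seed: int) -> list[TrialCondition]:
    """Build one participant's randomized 100-trial session.

    Each of the 10 (size level x location) cells occurs 10 times in total
    and exactly 5 times in each of the two 50-trial blocks; order is
    shuffled independently within each block.  The same seed reproduces
    the same list.
    """
    rng = np.random.default_rng(seed)
    cells = [
        (size, loc)
        for size in range(1, N_SIZE_LEVELS + 1)
        for loc in LOCATIONS
    ]
    reps_per_block = N_REPETITIONS // N_BLOCKS
    seen = {cell: 0 for cell in cells}
    trials: list[TrialCondition] = []
    for block in range(1, N_BLOCKS + 1):
        block_cells = [cell for cell in cells for _ in range(reps_per_block)]
        order = rng.permutation(len(block_cells))
        for idx, pos in enumerate(order, start=1):
            size, loc = block_cells[pos]
            seen[(size, loc)] += 1
            trials.append(
                TrialCondition(
                    size_level=size,
                    location=loc,
                    repetition=seen[(size, loc)],
                    block=block,
                    trial_index_in_block=idx,
                )
            )
    return trials


def trial_list_to_frame(
    participant_id: str | int, trials: Iterable[TrialCondition]
) -> pd.DataFrame:
    """Tabulate a trial list in the on-disk CSV layout."""
    rows = [
        {
            "participant_id": participant_id,
            "block": t.block,
            "trial": t.trial_index_in_block,
            "size_level": t.size_level,
            "location": t.location,
        }
        for t in trials
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AQ scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AQScore:
    """Summed AQ score with the clinical-recommendation flag (score >= 32)."""

    score: int
    clinical_flag: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0 <= self.score <= N_AQ_ITEMS:
            raise ValueError(f"AQ score out of range: {self.score}")
        object.__setattr__(self, "clinical_flag", self.score >= AQ_CLINICAL_CUTOFF)


def _response_is_agree(response: str) -> bool:
    if response not in RESPONSE_LEVELS:
        raise ValueError(f"invalid AQ response: {response!r}")
    return response.endswith("_agree") and not response.endswith("disagree")


def score_aq(
    responses: Sequence[str], scoring_key: Sequence[bool | int]
) -> AQScore:
    """Score a 50-item AQ response set.

    Each item contributes 1 point when the response pole (agree vs
    disagree, collapsing 'slightly' and 'strongly') matches the pole the
    scoring key marks as ASD-characteristic for that item.

    Parameters
    ----------
    responses
        Exactly 50 entries from :data:`RESPONSE_LEVELS`; missing entries
        (``None``) raise (no imputation).
    scoring_key
        Exactly 50 booleans; ``True`` when *agreeing* is the
        ASD-characteristic pole for the item.
    """
    if len(responses) != N_AQ_ITEMS:
        raise ValueError(f"expected {N_AQ_ITEMS} responses, got {len(responses)}")
    if len(scoring_key) != N_AQ_ITEMS:
        raise ValueError(f"expected {N_AQ_ITEMS} key entries, got {len(scoring_key)}")
    score = 0
    for i, (resp, agree_is_char) in enumerate(zip(responses, scoring_key), start=1):
        if resp is None:
            raise ValueError(f"missing response for item {i}")
        if _response_is_agree(resp) == bool(agree_is_char):
            score += 1
    return AQScore(score=score)


# Likert coding used in the AQ responses CSV (documented in its header).
_LIKERT_TO_RESPONSE = {1: "strongly_agree", 2: "slightly_agree",
                       3: "slightly_disagree", 4: "strongly_disagree"}


def load_aq_responses(path) -> dict[str, list[str]]:
    """Read per-participant AQ item responses from CSV.

    Columns: participant_id, item (1-50), response (1-4 Likert code:
    1=strongly_agree .. 4=strongly_disagree).  Returns item-ordered
    response lists keyed by participant.
    """
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[str]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("item")
        items = grp["item"].to_numpy()
        if len(items) != N_AQ_ITEMS or not np.array_equal(
            items, np.arange(1, N_AQ_ITEMS + 1)
        ):
            raise ValueError(f"participant {pid}: items must be exactly 1..50")
        try:
            responses = [_LIKERT_TO_RESPONSE[int(v)] for v in grp["response"]]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"participant {pid}: invalid Likert code") from exc
        out[str(pid)] = responses
    return out


def load_scoring_key(path) -> list[bool]:
    """Read the item scoring key (columns: item, agree_is_characteristic)."""
    df = pd.read_csv(path, comment="#").sort_values("item")
    if not np.array_equal(df["item"].to_numpy(), np.arange(1, N_AQ_ITEMS + 1)):
        raise ValueError("scoring key must cover items 1..50 exactly")
    return [bool(int(v)) for v in df["agree_is_characteristic"]]
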