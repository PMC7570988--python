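"""Sleep-stage alphabet and hypnogram container.

The package works with a four-stage hypnogram: Wake, REM, Light (the merge of
R&K S1+S2 / AASM N1+N2) and Deep (slow-wave sleep, R&K S3+S4 / AASM N3).
Stage indices are fixed — Wake=0, REM=1, Light=2, Deep=3 — and every matrix in
the staging model (transition rows/columns, emission rows) follows this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["Stage", "Hypnogram", "merge_reference_stages", "STAGE_CODES"]


class Stage(IntEnum):
    """Four-stage sleep alphabet with the model's fixed index order."""

    WAKE = 0
    REM = 1
    LIGHT = 2
    DEEP = 3

    @property
    def code(self) -> str:
        return STAGE_CODES[self.value]


#: single-letter codes used in hypnogram CSV output, index-aligned with Stage
STAGE_CODES = ("W", "R", "L", "D")

# recognized reference alphabets: R&K six-stage and AASM five-stage
_MERGE_MAP = {
    "W": Stage.WAKE,
    "R": Stage.REM,
    "REM": Stage.REM,
    "S1": Stage.LIGHT,
    "S2": Stage.LIGHT,
    "S3": Stage.DEEP,
    "S4": Stage.DEEP,
    "N1": Stage.LIGHT,
    "N2": Stage.LIGHT,
    "N3": Stage.DEEP,
    "1": Stage.LIGHT,
    "2": Stage.LIGHT,
    "3": Stage.DEEP,
    "4": Stage.DEEP,
}


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch sequence of sleep stages.

    Parameters
    ----------
    stages : array-like of int
        One ``Stage`` value per scoring epoch. Must be non-empty.
    epoch_seconds : float, default 30.0
        Duration of one scoring epoch in seconds.
    """

    stages: np.ndarray
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.stages, dtype=np.int8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("hypnogram must be a non-empty 1-D stage sequence")
        if not np.isin(arr, [s.value for s in Stage]).all():
            raise ValueError("hypnogram labels must be in {Wake, REM, Light, Deep}")
        if not self.epoch_seconds > 0:
            raise ValueError("epoch_seconds must be positive")
        object.__setattr__(self, "stages", arr)

    def __len__(self) -> int:
        return int(self.stages.size)

    @property
    def n_epochs(self) -> int:
        return len(self)

    @property
    def duration_minutes(self) -> float:
        return len(self) * self.epoch_seconds / 60.0

    def minutes_in(self, stage: Stage) -> float:
        """Total minutes spent in ``stage``."""
        return float(np.sum(self.stages == int(stage))) * self.epoch_seconds / 60.0

    @property
    def codes(self) -> list[str]:
        return [STAGE_CODES[s] for s in self.stages]

    def sleep_wake(self) -> np.ndarray:
        """Binary sleep (1) / wake (0) sequence at epoch resolution."""
        return (self.stages != int(Stage.WAKE)).astype(np.int8)


def merge_reference_stages(raw_labels, epoch_seconds: float = 30.0) -> Hypnogram:
    """Collapse R&K (W, R, S1–S4) or AASM (W, R, N1–N3) labels to four stages.

    W maps to Wake, R to REM, S1/S2/N1/N2 to Light and S3/S4/N3 to Deep.
    Movement/unscored labels are not accepted here; callers comparing against
    a reference drop those epochs pairwise first (see ``evaluation``).
    """
    labels = list(raw_labels)
    if not labels:
        raise ValueError("empty reference label sequence")
    merged = []
    for lab in labels:
        key = str(lab).strip().upper()
        if key not in _MERGE_MAP:
            raise ValueError(f"unrecognized reference stage label: {lab!r}")
        merged.append(int(_MERGE_MAP[key]))
    return Hypnogram(np.asarray(merged, dtype=np.int8), epoch_seconds=epoch_seconds)
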