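"""Clinical outcome events recorded during simulation."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OutcomeEvent", "EVENT_KINDS"]

EVENT_KINDS = ("stroke", "mi", "dementia", "non_cv_death", "cv_death")


@dataclass
class OutcomeEvent:
    """A dated clinical event for one person.

    ``fatal`` is meaningful only for stroke/MI.  ``rolled_back`` marks events
    retracted by population-level treatment recalibration; rolled-back events
    are excluded from all reporting.
    """

    person_id: int
    kind: str
    wave: int
    fatal: bool = False
    rolled_back: bool = False

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.fatal and self.kind not in ("stroke", "mi"):
            raise ValueError("fatal flag is only meaningful for stroke/mi events")
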