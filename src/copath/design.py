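"""Experimental design: the four-condition layout and its three contrasts.

Every differential-expression contrast is a treated condition versus the
shared baseline (non-injured, vehicle-treated animals):

* ``NC`` -- non-injured + drug vs baseline
* ``IV`` -- injured + vehicle vs baseline
* ``IC`` -- injured + drug vs baseline
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

BASELINE = "baseline"

#: Condition labels, baseline first.
CONDITIONS: tuple[str, ...] = (
    BASELINE,
    "noninjured_drug",
    "injured_vehicle",
    "injured_drug",
)

#: Contrast name -> treated condition compared against the baseline.
CONTRAST_CONDITIONS: dict[str, str] = {
    "NC": "noninjured_drug",
    "IV": "injured_vehicle",
    "IC": "injured_drug",
}

CONTRASTS: tuple[str, ...] = tuple(CONTRAST_CONDITIONS)


class DesignError(ValueError):
    """Raised when a sample sheet does not describe a valid design."""


@dataclass(frozen=True)
class SampleDesign:
    """Map each sample to one of the four conditions.

    Parameters
    ----------
    condition_of
        Mapping ``sample_id -> condition``; conditions must come from
        :data:`CONDITIONS` and the baseline must be present.
    """

    condition_of: dict[str, str]
    baseline: str = BASELINE
    _samples_by_condition: dict[str, list[str]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        unknown = sorted(set(self.condition_of.values()) - set(CONDITIONS))
        if unknown:
            raise DesignError(f"unknown condition(s): {', '.join(unknown)}")
        by_cond: dict[str, list[str]] = {c: [] for c in CONDITIONS}
        for sample, cond in self.condition_of.items():
            by_cond[cond].append(sample)
        if not by_cond[self.baseline]:
            raise DesignError(f"no samples assigned to baseline {self.baseline!r}")
        object.__setattr__(self, "_samples_by_condition", by_cond)

    @property
    def samples(self) -> list[str]:
        return list(self.condition_of)

    def samples_for(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise DesignError(f"unknown condition {condition!r}")
        return list(self._samples_by_condition[condition])

    def conditions_present(self) -> list[str]:
        return [c for c in CONDITIONS if self._samples_by_condition[c]]

    def require_complete(self) -> None:
        """Raise unless every one of the four conditions has >= 1 sample."""
        missing = [c for c in CONDITIONS if not self._samples_by_condition[c]]
        if missing:
            raise DesignError(f"missing condition(s): {', '.join(missing)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.condition_of), "condition": list(self.condition_of.values())}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        if {"sample_id", "condition"} - set(frame.columns):
            raise DesignError("sample sheet needs columns sample_id, condition")
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise DesignError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
        return cls(dict(zip(frame["sample_id"].astype(str), frame["condition"].astype(str))))
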