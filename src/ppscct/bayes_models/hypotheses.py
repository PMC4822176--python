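"""Hypothesis specifications: label assignments over effect parameters.

A hypothesis assigns each named effect a label; each label carries a
normal prior.  The reserved label ``"zero"`` is a structural constraint
(the effect is fixed at exactly 0 and has no free parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "Prior",
    "HypothesisSpec",
    "DEFAULT_LINEAR_PRIORS",
    "DEFAULT_LOGIT_PRIORS",
    "ZERO_LABEL",
]

ZERO_LABEL = "zero"


@dataclass(frozen=True)
class Prior:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")


# Effect-size priors on the ms scale of the ipsi-minus-contra CCE
# difference: "null" is a narrow normal at 0, "active" a broad normal at
# a plausible positive effect.  Both are configurable everywhere.
DEFAULT_LINEAR_PRIORS: Mapping[str, Prior] = MappingProxyType({
    "null": Prior(0.0, 5.0),
    "active": Prior(40.0, 20.0),
})

# Cell-level priors on the log-odds scale for Likert models.
DEFAULT_LOGIT_PRIORS: Mapping[str, Prior] = MappingProxyType({
    "low": Prior(-4.0, 2.0),
    "high": Prior(4.0, 2.0),
})


@dataclass(frozen=True)
class HypothesisSpec:
    """One element of a hypothesis space.

    ``effect_labels`` maps effect name -> label; ``priors`` maps label ->
    Prior.  Every non-"zero" label must have a prior.
    """

    id: str
    effect_labels: Mapping[str, str]
    priors: Mapping[str, Prior] = field(
        default_factory=lambda: DEFAULT_LINEAR_PRIORS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_labels",
                           MappingProxyType(dict(self.effect_labels)))
        object.__setattr__(self, "priors",
                           MappingProxyType(dict(self.priors)))
        for effect, label in self.effect_labels.items():
            if label != ZERO_LABEL and label not in self.priors:
                raise ValueError(
                    f"hypothesis {self.id!r}: effect {effect!r} has label "
                    f"{label!r} with no prior")

    @property
    def free_effects(self) -> list[str]:
        return [e for e, lab in self.effect_labels.items()
                if lab != ZERO_LABEL]

    def prior_for(self, effect: str) -> Prior:
        label = self.effect_labels[effect]
        if label == ZERO_LABEL:
            raise ValueError(f"effect {effect!r} is structurally zero")
        return self.priors[label]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "effect_labels": dict(self.effect_labels),
            "priors": {lab: {"mean": p.mean, "sd": p.sd}
                       for lab, p in self.priors.items()},
        }
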