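"""Likelihood-ratio calculator for probability of malignancy (pCa).

For an indeterminate solitary pulmonary nodule, each radiologic or clinical
feature contributes a likelihood ratio

    LR = (malignant nodules with the feature) / (benign nodules with the feature),

the odds of malignancy are the product of the feature LRs (including the
prevalence-based prior LR), and

    pCa = odds / (1 + odds).

An LR of 1.0 corresponds to a 50% chance of malignancy. The management rule
follows the cost-effectiveness thresholds: observation when pCa <= 0.05,
immediate resection when pCa >= 0.60, biopsy otherwise. This module is
included because the framework uses the same odds/probability conversion;
it is not a radiology tool (feature LR tables are user inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

#: Decision thresholds on pCa (overridable per call).
OBSERVATION_MAX = 0.05
RESECTION_MIN = 0.60


class FeatureLR(NamedTuple):
    """A named feature likelihood ratio."""

    name: str
    lr: float


@dataclass(frozen=True)
class PcaResult:
    odds: float
    pca: float
    decision: str  # observation | biopsy | resection


def likelihood_ratio(n_malignant_with_feature: int, n_benign_with_feature: int,
                     name: str = "feature", smoothing: bool = False) -> FeatureLR:
    """LR of one feature from malignant/benign counts.

    ``smoothing`` adds 0.5 to both counts (a continuity correction for zero
    cells); without it a zero benign count is an error.
    """
    if n_malignant_with_feature < 0 or n_benign_with_feature < 0:
        raise ValueError("counts must be non-negative")
    num, den = float(n_malignant_with_feature), float(n_benign_with_feature)
    if smoothing:
        num, den = num + 0.5, den + 0.5
    if den == 0:
        raise ValueError("benign count is zero; enable smoothing or supply counts")
    return FeatureLR(name, num / den)


def pca(lrs: Iterable[Union[FeatureLR, float]],
        observation_max: float = OBSERVATION_MAX,
        resection_min: float = RESECTION_MIN) -> PcaResult:
    """Probability of malignancy and management decision from feature LRs."""
    values = [lr.lr if isinstance(lr, FeatureLR) else float(lr) for lr in lrs]
    if not values:
        raise ValueError("need at least one likelihood ratio")
    for v in values:
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"likelihood ratios must be finite and >= 0, got {v}")
    odds = math.prod(values)
    p = odds / (1.0 + odds)
    if p <= observation_max:
        decision = "observation"
    elif p >= resection_min:
        decision = "resection"
    else:
        decision = "biopsy"
    return PcaResult(odds=odds, pca=p, decision=decision)
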