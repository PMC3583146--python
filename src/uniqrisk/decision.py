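"""The E1 decision rule combining the Pitman, SNB and Zayatz estimators.

No single estimator is accurate across all sampling fractions and
uniqueness levels, so the headline method selects among three of them:

    If pi <= 0.1:           use Pitman
    Else if SNB converged:
        if Est(SNB) > Est(Zayatz):  use Zayatz
        else:                       use SNB
    Else:                   use Zayatz

The mu-argus estimator is deliberately never consulted.  The returned
estimate is the chosen component's result object itself (bit-identical); if
the chosen component failed, its failed result is returned with the trace —
no secondary fallback is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Tuple

from .estimators import (
    EstimateResult,
    SamplingContext,
    estimate_pitman,
    estimate_snb,
    estimate_zayatz,
)
from .frequency import FrequencySpectrum

__all__ = ["DecisionTrace", "e1", "E1_COMPONENTS"]

E1_COMPONENTS = ("pitman", "snb", "zayatz")


@dataclass
class DecisionTrace:
    """Audit trail of the rule: which predicates fired and what was consulted."""

    chosen_estimator: str
    branch_path: List[Tuple[str, bool]] = field(default_factory=list)
    component_estimates: Dict[str, EstimateResult] = field(default_factory=dict)


def e1(
    spec: FrequencySpectrum,
    ctx: SamplingContext,
    estimator_impls: Optional[Mapping[str, Callable]] = None,
) -> Tuple[EstimateResult, DecisionTrace]:
    """Apply the decision rule; returns the chosen estimate and its trace.

    ``estimator_impls`` may override the component estimators (used for
    testing); keys 'pitman', 'snb', 'zayatz'.  The pi <= 0.1 comparison is
    exact (n/N at full precision, boundary inclusive).
    """
    impls = {
        "pitman": estimate_pitman,
        "snb": estimate_snb,
        "zayatz": estimate_zayatz,
    }
    if estimator_impls:
        impls.update(estimator_impls)

    branch: List[Tuple[str, bool]] = []
    components: Dict[str, EstimateResult] = {}

    small_fraction = ctx.pi <= 0.1
    branch.append(("pi<=0.1", small_fraction))
    if small_fraction:
        chosen = impls["pitman"](spec, ctx)
        components["pitman"] = chosen
        return chosen, DecisionTrace("pitman", branch, components)

    snb = impls["snb"](spec, ctx)
    components["snb"] = snb
    branch.append(("snb_converged", snb.converged))
    zayatz = impls["zayatz"](spec, ctx)
    components["zayatz"] = zayatz
    if not snb.converged:
        return zayatz, DecisionTrace("zayatz", branch, components)

    snb_greater = snb.lambda3_hat > zayatz.lambda3_hat
    branch.append(("snb_estimate_gt_zayatz", snb_greater))
    if snb_greater:
        return zayatz, DecisionTrace("zayatz", branch, components)
    return snb, DecisionTrace("snb", branch, components)
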