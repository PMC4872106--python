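"""Rule-based activity and toxicity classification of Ocr/pocr variants.

An Ocr variant is predicted active (antirestriction-competent) when it
meets all five charge/pI conditions simultaneously:

1. pI <= 4.5,
2. total acidic residues >= 14,
3. central ("orange") region acidic count >= 6 (of 9),
4. specific ("green") region acidic count >= 3,
5. flanking ("purple") share of the total <= 47 %.

Toxicity risk is predicted from a single, separate rule: a variant that is
not acidic at position 88 (helix D) loses the hydrogen bonds that pin down
loop 2 and tends to poison the host — so ``toxic_risk`` is raised whenever
position 88 is neutral.  The rule is a heuristic with known exceptions.

All comparisons are inclusive ("at least", "no more than", "4.5 or less");
the flanking percentage is compared as an exact rational
(100 * flanking <= threshold * total), never rounded first.  A variant with
no acidic residues has an undefined flanking percentage and fails closed.

``PartiallyActive`` exists only as an external label for imported
experimental datasets: the observed partially-active group overlaps the
inactive and toxic groups in charge composition, and no printed rule
separates them, so the classifier never emits it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .scaffold import (Artifact, BJELLQVIST, ChargeProfile, ChargeState,
                       PkaSet, ReferenceScaffold, charge_profile,
                       state_isoelectric_point)


class Phenotype(enum.Enum):
    ACTIVE = "Active"
    INACTIVE = "Inactive"
    PARTIALLY_ACTIVE = "PartiallyActive"
    TOXIC = "Toxic"
    NON_EXPRESSING = "NonExpressing"


@dataclass(frozen=True)
class RuleThresholds:
    """Thresholds of the activity/toxicity rule (all bounds inclusive)."""

    pi_max: float = 4.5
    total_min: int = 14
    central_min: int = 6
    flanking_pct_max: float = 47.0
    specific_min: int = 3
    require_pos88_acidic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_max < 14.0:
            raise ValueError(f"pi_max={self.pi_max} outside (0, 14)")
        if not 0.0 <= self.flanking_pct_max <= 100.0:
            raise ValueError(
                f"flanking_pct_max={self.flanking_pct_max} outside [0, 100]")
        for name in ("total_min", "central_min", "specific_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclass(frozen=True)
class ActivityCall:
    """Classifier verdict for one clone.

    ``active`` is True iff all five charge/pI conditions pass;
    ``toxic_risk`` is True iff position 88 is not acidic (when the rule is
    enabled).  The phenotype is Active for active non-toxic clones, Toxic
    for active clones with a neutral position 88 (which the screen still
    recovers — activity and toxicity are independent axes), Inactive
    otherwise.  Artifact clones are NonExpressing with an empty trace.
    """

    active: bool
    toxic_risk: bool
    phenotype: Phenotype
    trace: Mapping[str, bool] = field(default_factory=dict)
    pI_value: float | None = None


def classify(profile: ChargeProfile, pI: float,
             thresholds: RuleThresholds = DEFAULT_THRESHOLDS) -> ActivityCall:
    """Apply the activity/toxicity rule to an intact clone's profile."""
    t = thresholds
    # Exact rational comparison for the flanking share; undefined -> fail.
    flanking_ok = (profile.total > 0
                   and 100.0 * profile.flanking
                   <= t.flanking_pct_max * profile.total)
    trace = {
        "pI": pI <= t.pi_max,
        "total": profile.total >= t.total_min,
        "central": profile.central >= t.central_min,
        "specific": profile.specific >= t.specific_min,
        "flanking_pct": flanking_ok,
        "pos88": profile.pos88_acidic,
    }
    active = (trace["pI"] and trace["total"] and trace["central"]
              and trace["specific"] and trace["flanking_pct"])
    toxic_risk = t.require_pos88_acidic and not profile.pos88_acidic
    # Phenotype precedence: the Toxic call is reserved for clones that are
    # otherwise active (the 3.11 situation: full antirestriction activity,
    # toxic on overexpression).  A clone failing the charge rules is called
    # Inactive even when position 88 is neutral — pocr itself is inactive,
    # not toxic — though its toxic_risk flag is still raised.
    if active and toxic_risk:
        phenotype = Phenotype.TOXIC
    elif active:
        phenotype = Phenotype.ACTIVE
    else:
        phenotype = Phenotype.INACTIVE
    return ActivityCall(active=active, toxic_risk=toxic_risk,
                        phenotype=phenotype, trace=trace, pI_value=pI)


def classify_clone(state: ChargeState,
                   thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
                   pka: PkaSet = BJELLQVIST) -> ActivityCall:
    """Classify a clone end to end (profile + pI + rule).

    Artifact clones (frameshift/deletion or empty vector) are routed to
    ``NonExpressing`` without touching their charge vector.
    """
    if state.artifact is not Artifact.INTACT:
        return ActivityCall(active=False, toxic_risk=False,
                            phenotype=Phenotype.NON_EXPRESSING, trace={},
                            pI_value=None)
    profile = charge_profile(state)
    pI = state_isoelectric_point(state, pka)
    return classify(profile, pI, thresholds)


def thresholds_from_config(config: Mapping) -> RuleThresholds:
    """Build thresholds from a ``rules:`` config block (missing keys keep
    their defaults)."""
    block = config.get("rules", config)
    kwargs = {}
    for name in ("pi_max", "total_min", "central_min", "flanking_pct_max",
                 "specific_min", "require_pos88_acidic"):
        if name in block:
            kwargs[name] = block[name]
    return RuleThresholds(**kwargs)
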