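"""Evidence algebra for socially grounded belief evaluation.

The reliability of a concept (or the preference for an action) ``j`` from
the point of view of an agent ``i`` is the product of two supports:

* *believed evidence* — compatibility of ``j`` with the agent's own core
  belief items ``l``, each weighted by the mental attachment ``B_il``;
* *social evidence* — approval of ``j`` by peers ``k``, each weighted by
  the social attachment ``S_ik``.

The raw product grows with the size of the belief and social bases, so a
normalized form divides each factor by its total attachment mass, yielding
a value in [0, 1].  The same weighted-average shape underlies the revision
rule for combining observations (strength ``f`` weighted by evidence mass
``D`` derived from confidence ``c``) and the probabilistic reliability of a
rule over a set of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Convention",
    "BeliefAttachment",
    "SocialAttachment",
    "BelievedEvidence",
    "SocialEvidence",
    "EvidenceEstimate",
    "Observation",
    "RuleSatisfaction",
    "evidence_weight",
    "raw_evidence",
    "normalized_evidence",
    "revision",
    "probabilistic_reliability",
]


class Convention(str, Enum):
    """How the evidence mass ``D`` is derived from a confidence ``c``.

    ``STRENGTH`` uses ``D = c`` directly; ``FREQUENCY_ODDS`` uses the odds
    transform ``D = c / (1 - c)``, which requires ``c < 1`` strictly.
    """

    STRENGTH = "strength"
    FREQUENCY_ODDS = "frequency_odds"


def _check_unit(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class BeliefAttachment:
    """Mental attachment ``B_il`` of agent ``i`` to belief item ``l``."""

    agent_id: str
    item_id: str
    weight: float

    def __post_init__(self) -> None:
        _check_unit(self.weight, "belief attachment weight")


@dataclass(frozen=True)
class SocialAttachment:
    """Social attachment ``S_ik`` of agent ``i`` to peer ``k``."""

    agent_id: str
    peer_id: str
    weight: float

    def __post_init__(self) -> None:
        _check_unit(self.weight, "social attachment weight")
        if self.agent_id == self.peer_id:
            raise ValueError("an agent cannot hold a social attachment to itself")


@dataclass(frozen=True)
class BelievedEvidence:
    """Compatibility of concept ``j`` with belief item ``l`` for agent ``i``."""

    agent_id: str
    concept_id: str
    item_id: str
    value: float
    cached: bool = False

    def __post_init__(self) -> None:
        _check_unit(self.value, "believed evidence value")


@dataclass(frozen=True)
class SocialEvidence:
    """Approval of concept ``j`` by peer ``k`` in the view of agent ``i``."""

    agent_id: str
    concept_id: str
    peer_id: str
    value: float
    cached: bool = False

    def __post_init__(self) -> None:
        _check_unit(self.value, "social evidence value")


@dataclass(frozen=True)
class EvidenceEstimate:
    """Result of a believed-social-evidence evaluation.

    ``raw`` is the un-normalized product of sums; ``normalized`` lies in
    [0, 1] whenever all inputs do.  ``provenance`` records how the value was
    obtained: freshly ``computed``, read from a ``cached`` entry, or
    ``defaulted`` when a factor (or the whole value) had to fall back to a
    documented default.
    """

    raw: float
    normalized: float
    timestamp: int = 0
    provenance: str = "computed"


@dataclass(frozen=True)
class Observation:
    """A single observation supporting a generalized proposition.

    ``strength`` is the observed frequency/strength ``f`` in [0, 1];
    ``confidence`` is ``c`` in [0, 1); ``evidence_weight`` is the derived
    mass ``D`` under the given convention.
    """

    strength: float
    confidence: float
    convention: Convention = Convention.STRENGTH
    evidence_weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_unit(self.strength, "observation strength")
        conv = Convention(self.convention)
        object.__setattr__(self, "convention", conv)
        derived = evidence_weight(self.confidence, conv)
        if self.evidence_weight is None:
            object.__setattr__(self, "evidence_weight", derived)
        elif abs(self.evidence_weight - derived) > 1e-12:
            raise ValueError(
                f"evidence_weight {self.evidence_weight!r} inconsistent with "
                f"confidence {self.confidence!r} under convention {conv.value}"
            )


@dataclass(frozen=True)
class RuleSatisfaction:
    """Per-observation satisfaction indicators of a rule confirming a fact.

    Indicators may be graded in [0, 1]; boolean inputs map to 0/1.  When
    ``weights`` is None all observations carry equal evidence mass.
    """

    indicators: tuple
    weights: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        inds = tuple(float(i) for i in self.indicators)
        if len(inds) < 1:
            raise ValueError("at least one observation indicator required")
        for phi in inds:
            _check_unit(phi, "satisfaction indicator")
        object.__setattr__(self, "indicators", inds)
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(inds):
                raise ValueError("one weight per indicator required")
            if any(x < 0 for x in w):
                raise ValueError("evidence weights must be non-negative")
            object.__setattr__(self, "weights", w)


def evidence_weight(confidence: float, convention: Convention | str = Convention.STRENGTH) -> float:
    """Derive the evidence mass ``D`` from a confidence ``c``.

    Under the ``strength`` convention ``D = c``; under ``frequency_odds``
    ``D = c / (1 - c)``, undefined at ``c = 1``.
    """
    conv = Convention(convention)
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence must lie in [0, 1], got {confidence!r}")
    if conv is Convention.FREQUENCY_ODDS:
        if confidence >= 1.0:
            raise ValueError(
                "confidence must be strictly below 1 under the frequency_odds convention"
            )
        return confidence / (1.0 - confidence)
    return float(confidence)


def _validated_pairs(pairs: Iterable[tuple], kind: str) -> list[tuple[float, float]]:
    out = []
    for value, weight in pairs:
        out.append(
            (
                _check_unit(float(value), f"{kind} evidence component"),
                _check_unit(float(weight), f"{kind} attachment weight"),
            )
        )
    return out


def raw_evidence(
    believed: Sequence[tuple], social: Sequence[tuple]
) -> float:
    """Un-normalized believed social evidence ``E_ij``.

    ``E_ij = (Σ_l E^B·B) · (Σ_k E^S·S)``.  An empty base contributes a zero
    factor, so the product vanishes.  Grows with base size; see
    :func:`normalized_evidence` for the bounded form.
    """
    b = _validated_pairs(believed, "believed")
    s = _validated_pairs(social, "social")
    return sum(e * w for e, w in b) * sum(e * w for e, w in s)


def normalized_evidence(
    believed: Sequence[tuple],
    social: Sequence[tuple],
    timestamp: int = 0,
) -> EvidenceEstimate:
    """Normalized believed social evidence ``Ẽ_ij`` in [0, 1].

    Each factor is the attachment-weighted mean of its evidence values:
    ``Ẽ = (Σ E^B·B / Σ B) · (Σ E^S·S / Σ S)``.  A factor whose base is
    empty or carries zero total attachment defaults to 1.0 — a solitary
    agent falls back entirely on the other factor — and the estimate is
    marked ``defaulted``.  Raises if both bases are empty.
    """
    b = _validated_pairs(believed, "believed")
    s = _validated_pairs(social, "social")
    if not b and not s:
        raise ValueError("nothing to evaluate: both evidence bases are empty")
    provenance = "computed"
    factors = []
    for pairs in (b, s):
        mass = sum(w for _, w in pairs)
        if mass > 0:
            factors.append(sum(e * w for e, w in pairs) / mass)
        else:
            factors.append(1.0)
            provenance = "defaulted"
    raw = sum(e * w for e, w in b) * sum(e * w for e, w in s)
    return EvidenceEstimate(
        raw=raw,
        normalized=factors[0] * factors[1],
        timestamp=timestamp,
        provenance=provenance,
    )


def revision(observations: Sequence[Observation]) -> float:
    """Revision rule: combine observation strengths into one estimate.

    ``F_rev = Σ f_j·D_j / Σ D_j`` — the evidence-mass-weighted mean of the
    observation strengths, guaranteed to lie within [min f, max f].
    """
    if not observations:
        raise ValueError("at least one observation required")
    total = sum(o.evidence_weight for o in observations)
    if total <= 0:
        raise ValueError("no evidence mass: all observation weights are zero")
    return sum(o.strength * o.evidence_weight for o in observations) / total


def probabilistic_reliability(satisfactions: RuleSatisfaction) -> float:
    """Probabilistic reliability ``ν`` of a fact over a set of observations.

    ``ν = Σ Φ_g·D_g / Σ D_g``; with equal weights this reduces to the plain
    satisfaction ratio ``Σ Φ_g / G``.
    """
    inds = satisfactions.indicators
    weights = satisfactions.weights
    if weights is None:
        weights = tuple(1.0 for _ in inds)
    total = sum(weights)
    if total <= 0:
        raise ValueError("no evidence mass: total weight is zero")
    return sum(phi * w for phi, w in zip(inds, weights)) / total
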