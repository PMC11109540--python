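"""The nine-mode genotype error/missingness specification.

Each mode is a directed genotype-class transition named by source and target:
the first two letters encode the source class (``ra`` = het, ``rr`` =
hom-ref, ``aa`` = hom-alt) and the last two the target (``rr``, ``ra``,
``aa``, or ``mm`` = missing). Three modes apply to each of the three diploid
biallelic source classes:

======  ==========  ==========
mode    source      target
======  ==========  ==========
rarr    het         hom-ref   (heterozygous drop-out)
raaa    het         hom-alt
ramm    het         missing
rrra    hom-ref     het       (drop-in)
rraa    hom-ref     hom-alt
rrmm    hom-ref     missing
aara    hom-alt     het
aarr    hom-alt     hom-ref
aamm    hom-alt     missing
======  ==========  ==========

A genotype is perturbed by a single categorical draw over its class's
outcomes — the applicable modes plus a stay-unchanged outcome whose mass is
the complement — so the three per-class probability sums must each be ≤ 1.
Missing input genotypes have no transitions: no mode resurrects a missing
call.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, List, Tuple

from .vcf_io import GTClass

__all__ = [
    "MODES",
    "MODE_SOURCE",
    "MODE_TARGET",
    "MODES_BY_SOURCE",
    "ErrorSpec",
    "ErrorSpecError",
    "TransitionDistribution",
    "validate_spec",
    "transition_for",
]


class ErrorSpecError(ValueError):
    """An error specification violates the model's constraints."""


#: Mode name -> (source class, target class).
_MODE_TABLE: Dict[str, Tuple[GTClass, GTClass]] = {
    "rarr": (GTClass.HET, GTClass.HOM_REF),
    "raaa": (GTClass.HET, GTClass.HOM_ALT),
    "ramm": (GTClass.HET, GTClass.MISSING),
    "rrra": (GTClass.HOM_REF, GTClass.HET),
    "rraa": (GTClass.HOM_REF, GTClass.HOM_ALT),
    "rrmm": (GTClass.HOM_REF, GTClass.MISSING),
    "aara": (GTClass.HOM_ALT, GTClass.HET),
    "aarr": (GTClass.HOM_ALT, GTClass.HOM_REF),
    "aamm": (GTClass.HOM_ALT, GTClass.MISSING),
}

MODES: Tuple[str, ...] = tuple(_MODE_TABLE)
MODE_SOURCE: Dict[str, GTClass] = {m: s for m, (s, _) in _MODE_TABLE.items()}
MODE_TARGET: Dict[str, GTClass] = {m: t for m, (_, t) in _MODE_TABLE.items()}
MODES_BY_SOURCE: Dict[GTClass, Tuple[str, ...]] = {
    klass: tuple(m for m in MODES if MODE_SOURCE[m] is klass)
    for klass in (GTClass.HET, GTClass.HOM_REF, GTClass.HOM_ALT)
}

_CLASS_LABEL = {GTClass.HET: "HET", GTClass.HOM_REF: "HOM_REF", GTClass.HOM_ALT: "HOM_ALT"}


@dataclass(frozen=True)
class ErrorSpec:
    """Per-mode error/missingness probabilities; unspecified modes are 0."""

    p_rarr: float = 0.0
    p_raaa: float = 0.0
    p_ramm: float = 0.0
    p_rrra: float = 0.0
    p_rraa: float = 0.0
    p_rrmm: float = 0.0
    p_aara: float = 0.0
    p_aarr: float = 0.0
    p_aamm: float = 0.0

    def probability(self, mode: str) -> float:
        return getattr(self, f"p_{mode}")

    @classmethod
    def single_mode(cls, mode: str, rate: float) -> "ErrorSpec":
        if mode not in MODES:
            raise ErrorSpecError(f"unknown error mode {mode!r} (expected one of {', '.join(MODES)})")
        return cls(**{f"p_{mode}": rate})

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class TransitionDistribution:
    """Outcome distribution for one source genotype class.

    ``outcomes`` is an ordered list of ``(target class, mode-or-None,
    probability)``; the final entry is the stay-unchanged outcome (mode
    ``None``) with the complementary mass, so probabilities sum to 1.
    """

    source_klass: GTClass
    outcomes: Tuple[Tuple[GTClass, object, float], ...]


def validate_spec(spec: ErrorSpec) -> ErrorSpec:
    """Validate the nine probabilities; returns ``spec`` unchanged.

    Each probability must lie in [0, 1] and the three per-source-class sums
    must each be ≤ 1 (they share one categorical draw). Over-unit class mass
    is rejected rather than renormalized.
    """
    for mode in MODES:
        p = spec.probability(mode)
        if not (0.0 <= p <= 1.0):
            raise ErrorSpecError(f"--p_{mode} must be in [0, 1], got {p!r}")
    for klass, modes in MODES_BY_SOURCE.items():
        total = sum(spec.probability(m) for m in modes)
        if total > 1.0 + 1e-12:
            raise ErrorSpecError(
                f"{_CLASS_LABEL[klass]} mass {total:g} > 1 "
                f"(sum of {', '.join('--p_' + m for m in modes)})"
            )
    return spec


def transition_for(spec: ErrorSpec, klass: GTClass) -> TransitionDistribution:
    """Outcome distribution for genotypes of class ``klass`` under ``spec``.

    Defined only for the three diploid biallelic classes; MISSING and OTHER
    calls have no transitions and must be passed through by the caller.
    """
    if klass not in MODES_BY_SOURCE:
        raise ErrorSpecError(f"no transitions defined for {klass.name} genotypes")
    outcomes: List[Tuple[GTClass, object, float]] = []
    stay = 1.0
    for mode in MODES_BY_SOURCE[klass]:
        p = spec.probability(mode)
        outcomes.append((MODE_TARGET[mode], mode, p))
        stay -= p
    outcomes.append((klass, None, max(stay, 0.0)))
    return TransitionDistribution(source_klass=klass, outcomes=tuple(outcomes))
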