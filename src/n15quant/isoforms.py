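"""Shared-peptide isoform arithmetic.

A peptide shared by several isoforms reports the abundance-weighted mean of
their individual heavy fractions: ``q_shared = Σ w_i q_i``.  With two
components whose own q-values are known from unique peptides, the observed
shared q inverts to the isoform weight ratio — e.g. unique q-values of 0.60
and 0.34 predict a shared q of 0.47 at equal amounts, so an observed 0.39
implies the second isoform is roughly four times as abundant as the first.
The arithmetic assumes the shared peptide ionizes and is detected with equal
efficiency from every parent isoform.

Inversion divides by (q1 − q2), so nearly equal component q-values make the
ratio ill-conditioned; a warning is raised below a 0.1 separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "predict_shared_q",
    "invert_two_component",
    "family_bounds",
    "round_1sf",
    "TwoComponentResult",
    "FamilyBounds",
    "CONDITIONING_SEPARATION",
]

#: Below this |q1 − q2| separation the two-component inversion is flagged
#: as ill-conditioned.
CONDITIONING_SEPARATION = 0.1

#: The shared-peptide arithmetic assumes equal ionization/detection
#: efficiency of the peptide across its parent isoforms.
EQUAL_EFFICIENCY_ASSUMPTION = (
    "assumes equal ionization/detection efficiency across isoforms"
)


class IsoformError(ValueError):
    """Raised for invalid isoform-mixture inputs."""


def _check_q(name: str, q: float) -> None:
    if not 0.0 <= q <= 1.0:
        raise IsoformError(f"{name}={q} outside [0, 1]")


def predict_shared_q(
    weights: Sequence[float], component_qs: Sequence[float]
) -> float:
    """Forward model: q of a shared peptide from isoform abundance weights.

    ``weights`` are abundance fractions summing to 1; the result is their
    weighted mean of the component q-values and always lies within
    [min q_i, max q_i].
    """
    if len(weights) != len(component_qs):
        raise IsoformError(
            f"{len(weights)} weights but {len(component_qs)} component q-values"
        )
    if not weights:
        raise IsoformError("empty mixture")
    if any(w < 0 for w in weights):
        raise IsoformError("negative abundance weight")
    total = sum(weights)
    if abs(total - 1.0) > 1e-9:
        raise IsoformError(f"weights sum to {total}, expected 1")
    for q in component_qs:
        _check_q("component q", q)
    return float(sum(w * q for w, q in zip(weights, component_qs)))


def round_1sf(x: float) -> float:
    """Round to one significant figure ('about 4×', 'about 10/1')."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent)


@dataclass(frozen=True)
class TwoComponentResult:
    """Inversion of a two-isoform shared q to abundance weights.

    ``ratio`` is component-2 : component-1 abundance (w2/w1).  When the
    exact solution falls outside the weight simplex the result is marked
    infeasible and the clamped boundary solution is reported instead.
    ``ill_conditioned`` warns that |q1 − q2| is small, so the ratio is
    highly sensitive to q-value error.
    """

    w1: float
    w2: float
    ratio: float
    ratio_rounded: float
    feasible: bool
    ill_conditioned: bool
    assumption: str = EQUAL_EFFICIENCY_ASSUMPTION


def invert_two_component(
    q_shared: float, q1: float, q2: float
) -> TwoComponentResult:
    """Solve q_shared = w1·q1 + (1−w1)·q2 for the abundance weights."""
    _check_q("q_shared", q_shared)
    _check_q("q1", q1)
    _check_q("q2", q2)
    if q1 == q2:
        raise IsoformError(
            "q1 == q2: mixture weights are unidentifiable from the shared q"
        )
    w1_exact = (q_shared - q2) / (q1 - q2)
    feasible = 0.0 <= w1_exact <= 1.0
    w1 = min(max(w1_exact, 0.0), 1.0)
    w2 = 1.0 - w1
    ratio = math.inf if w1 == 0 else w2 / w1
    return TwoComponentResult(
        w1=w1,
        w2=w2,
        ratio=ratio,
        ratio_rounded=round_1sf(ratio),
        feasible=feasible,
        ill_conditioned=abs(q1 - q2) < CONDITIONING_SEPARATION,
    )


@dataclass(frozen=True)
class FamilyBounds:
    """Feasibility description for a peptide shared by ≥3 isoforms.

    With three or more free weights no point estimate exists; the module
    reports whether the observed shared q is consistent with the known
    component q-values, which components lack a unique-peptide q, the
    family-level heavy:light ratio q/(1−q) (the shared peptide read as a
    family aggregate), and — when exactly one component q is unknown — the
    interval of values for it compatible with the observation.
    """

    feasible: bool | None
    known_range: tuple[float, float] | None
    unknown_components: tuple[int, ...]
    family_fold: float
    unknown_q_interval: tuple[float, float] | None
    assumption: str = EQUAL_EFFICIENCY_ASSUMPTION


def family_bounds(
    q_shared: float, component_qs: Sequence[float | None]
) -> FamilyBounds:
    """Feasible-region description for a shared peptide of a ≥3 family.

    ``component_qs`` holds the unique-peptide q of each isoform, or None
    where no unique peptide quantified it.  Feasibility requires q_shared
    to lie within [min q_i, max q_i] of the known components; any unknown
    component can only widen that interval toward the side it would need
    to cover, which is what ``unknown_q_interval`` reports when a single
    component is unknown.
    """
    _check_q("q_shared", q_shared)
    if len(component_qs) < 3:
        raise IsoformError("family_bounds needs >=3 components")
    known = [q for q in component_qs if q is not None]
    unknown = tuple(i for i, q in enumerate(component_qs) if q is None)
    for q in known:
        _check_q("component q", q)

    eps = 1e-12
    if not known:
        return FamilyBounds(
            feasible=None,
            known_range=None,
            unknown_components=unknown,
            family_fold=q_shared / (1.0 - q_shared) if q_shared < 1 else math.inf,
            unknown_q_interval=None,
        )

    lo, hi = min(known), max(known)
    within = lo - eps <= q_shared <= hi + eps
    interval = None
    if len(unknown) == 1:
        # the unknown component must be able to pull the mixture mean to
        # q_shared: unconstrained if already covered by the known range,
        # otherwise it must lie at or beyond the observation
        if within:
            interval = (0.0, 1.0)
        elif q_shared > hi:
            interval = (q_shared, 1.0)
        else:
            interval = (0.0, q_shared)
    feasible = True if (within or unknown) else False
    return FamilyBounds(
        feasible=feasible,
        known_range=(lo, hi),
        unknown_components=unknown,
        family_fold=q_shared / (1.0 - q_shared) if q_shared < 1 else math.inf,
        unknown_q_interval=interval,
    )
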