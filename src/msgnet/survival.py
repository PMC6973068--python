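"""Survival model for an individual joining conspecific or heterospecific groups.

The model follows a single focal individual of species F that joins a group of
``N_T`` individuals of a target species T (conspecifics share the focal's
traits) in a community preyed on by a set of predators P. Survival emerges
from three processes:

detection
    The focal escapes an attack if the predator is detected, either by its own
    vigilance or via alarm calls from group members:
    ``x = V_F + V_T * A_PT * R_TF * N_T`` saturating as ``X = x / (x + c1)``,
    where ``V`` is the proportion of time vigilant, ``A_PT`` the target's
    probability of alarm calling at predator P, and ``R_TF`` the relevance of
    the target's alarm call to the focal.

dilution
    If the attack goes undetected, the chance of not being the victim depends
    on relative predator vulnerability ``Z``:
    ``Y = 1 - Z_PF / (Z_PF + Z_PT * N_T)`` (defined as 1 when the denominator
    is zero — nobody in the group is vulnerable, so nobody is taken).

resource competition
    The group consumes ``k = (C_F + N_T * C_T) / C_tot`` of the patch, mapped
    to a mortality probability through a logistic
    ``K = 1 / (1 + exp(-c2 * (k - c3)))``.

A predator encountering the group targets it with probability
``L_P = max(Z_PF, Z_PT)`` (preference for the most preferred prey present).
Death by predation compounds over predators weighted by each predator's share
``Q_P`` of community-wide prey consumption:
``D = 1 - prod_P (1 - Q_P * L_P * (1 - X_PF) * (1 - Y_PF))``,
and overall survival is ``S = (1 - D) * (1 - K)``.

All kernels broadcast over numpy arrays so large trait grids evaluate in one
vectorised pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ModelConstants",
    "SpeciesTraits",
    "PredatorSpec",
    "GroupScenario",
    "SurvivalBreakdown",
    "target_selection_prob",
    "detection_prob",
    "dilution_prob",
    "death_prob",
    "competition_cost",
    "survival",
    "scenario_breakdown",
    "expected_survival",
    "validate_predator_set",
]


def _check_range(x, name, lo=None, hi=None):
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if lo is not None and np.any(arr < lo):
        raise ValidationError(f"{name} must be >= {lo}")
    if hi is not None and np.any(arr > hi):
        raise ValidationError(f"{name} must be <= {hi}")
    return arr


@dataclass(frozen=True)
class ModelConstants:
    """Constants of the survival model.

    ``c1`` sets how fast detection saturates, ``c2`` the steepness and ``c3``
    the inflection of the competition logistic, and ``c_tot`` the total
    resources at the patch. The default ``c_tot`` places a unit-consumption
    conspecific group at the median scan size (N_T = 10) exactly at the
    logistic inflection: (1 + 10·1) / 0.5 = 22.
    """

    c1: float = 0.8
    c2: float = 10.0
    c3: float = 0.5
    c_tot: float = 22.0

    def __post_init__(self):
        if not self.c1 > 0:
            raise ConfigurationError("c1 must be > 0")
        if not self.c_tot > 0:
            raise ConfigurationError("c_tot must be > 0")


@dataclass(frozen=True)
class SpeciesTraits:
    """Scalar traits of one species.

    ``alarm_prob`` and ``vulnerability`` map predator ids to probabilities;
    ``consumption`` is per-individual resource intake (arbitrary units ≥ 0).
    """

    id: str
    vigilance: float
    alarm_prob: Mapping[str, float]
    vulnerability: Mapping[str, float]
    consumption: float

    def __post_init__(self):
        _check_range(self.vigilance, f"{self.id}.vigilance", 0.0, 1.0)
        for pred, a in self.alarm_prob.items():
            _check_range(a, f"{self.id}.alarm_prob[{pred}]", 0.0, 1.0)
        for pred, z in self.vulnerability.items():
            _check_range(z, f"{self.id}.vulnerability[{pred}]", 0.0, 1.0)
        _check_range(self.consumption, f"{self.id}.consumption", 0.0)


@dataclass(frozen=True)
class PredatorSpec:
    """A predator and its share of total prey biomass consumed (``Q_P``)."""

    id: str
    pressure: float

    def __post_init__(self):
        _check_range(self.pressure, f"{self.id}.pressure", 0.0, 1.0)


def validate_predator_set(predators: Sequence[PredatorSpec], tol: float = 1e-6):
    total = sum(p.pressure for p in predators)
    if predators and abs(total - 1.0) > tol:
        raise ValidationError(f"predator pressures must sum to 1, got {total}")


@dataclass(frozen=True)
class GroupScenario:
    """One focal/target/group-size configuration."""

    focal: SpeciesTraits
    target: SpeciesTraits
    relevance: float
    n_target: int
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self):
        _check_range(self.relevance, "relevance", 0.0, 1.0)
        if self.n_target < 0:
            raise ValidationError("n_target must be >= 0")


@dataclass(frozen=True)
class SurvivalBreakdown:
    """Per-predator and aggregate components of a scenario's survival."""

    predators: tuple
    selection: np.ndarray  # L_P
    detection: np.ndarray  # X_PF
    dilution: np.ndarray  # Y_PF
    death: float  # D_F
    competition_k: float  # k_F
    competition: float  # K_F
    survival: float  # S_F


def target_selection_prob(z_focal, z_target):
    """Probability ``L_P`` that a predator encountering the group targets it.

    Equals the predator's preference for the most preferred prey present,
    ``max(Z_PF, Z_PT)``.
    """
    zf = _check_range(z_focal, "z_focal", 0.0, 1.0)
    zt = _check_range(z_target, "z_target", 0.0, 1.0)
    return np.maximum(zf, zt)


def detection_prob(v_focal, v_target, alarm_prob, relevance, n_target, c1=0.8):
    """Probability ``X_PF`` that the focal detects an attacking predator.

    Raw detection ``x = V_F + V_T A_PT R_TF N_T`` saturates as
    ``X = x / (x + c1)``; zero information gives X = 0 and X < 1 always.
    """
    if not np.all(np.asarray(c1) > 0):
        raise ConfigurationError("c1 must be > 0")
    vf = _check_range(v_focal, "v_focal", 0.0, 1.0)
    vt = _check_range(v_target, "v_target", 0.0, 1.0)
    a = _check_range(alarm_prob, "alarm_prob", 0.0, 1.0)
    r = _check_range(relevance, "relevance", 0.0, 1.0)
    n = _check_range(n_target, "n_target", 0.0)
    x = vf + vt * a * r * n
    return x / (x + c1)


def dilution_prob(z_focal, z_target, n_target):
    """Probability ``Y_PF`` of not being the victim of an undetected attack.

    ``Y = 1 - Z_PF / (Z_PF + Z_PT N_T)``, with Y = 1 on a zero denominator
    (no vulnerable individual for the predator to take).
    """
    zf = _check_range(z_focal, "z_focal", 0.0, 1.0)
    zt = _check_range(z_target, "z_target", 0.0, 1.0)
    n = _check_range(n_target, "n_target", 0.0)
    denom = zf + zt * n
    safe = np.where(denom == 0, 1.0, denom)
    return np.where(denom == 0, 1.0, 1.0 - zf / safe)


def death_prob(predators):
    """Overall probability ``D_F`` of death by predation.

    ``predators`` is a sequence of ``(Q_P, L_P, X_PF, Y_PF)`` tuples; the
    per-predator death chances compound multiplicatively:
    ``D = 1 - prod(1 - Q L (1-X)(1-Y))``. An empty sequence means no
    predation (D = 0, with a warning).
    """
    predators = list(predators)
    if not predators:
        warnings.warn("empty predator set: death probability is 0", stacklevel=2)
        return 0.0
    q, l, x, y = (np.asarray(v, dtype=float) for v in zip(*predators))
    for name, arr in (("Q", q), ("L", l), ("X", x), ("Y", y)):
        _check_range(arr, name, 0.0, 1.0)
    return float(1.0 - np.prod(1.0 - q * l * (1.0 - x) * (1.0 - y)))


def competition_cost(c_focal, c_target, n_target, c_tot=22.0, c2=10.0, c3=0.5):
    """Resource-competition load ``k_F`` and mortality ``K_F``.

    ``k = (C_F + N_T C_T) / C_tot`` is the share of patch resources the group
    consumes; ``K = 1 / (1 + exp(-c2 (k - c3)))`` maps it to (0, 1) with
    K = 0.5 exactly at ``k = c3``.
    """
    if not np.all(np.asarray(c_tot) > 0):
        raise ConfigurationError("c_tot must be > 0")
    cf = _check_range(c_focal, "c_focal", 0.0)
    ct = _check_range(c_target, "c_target", 0.0)
    n = _check_range(n_target, "n_target", 0.0)
    k = (cf + n * ct) / c_tot
    big_k = 1.0 / (1.0 + np.exp(-c2 * (k - c3)))
    return k, big_k


def survival(death, competition):
    """Overall survival ``S_F = (1 - D_F)(1 - K_F)``."""
    d = _check_range(death, "death", 0.0, 1.0)
    k = _check_range(competition, "competition", 0.0, 1.0)
    return (1.0 - d) * (1.0 - k)


def scenario_breakdown(
    focal: SpeciesTraits,
    target: SpeciesTraits,
    relevance: float,
    n_target: int,
    predators: Sequence[PredatorSpec],
    constants: ModelConstants | None = None,
) -> SurvivalBreakdown:
    """Evaluate every model component for one focal/target/size scenario."""
    constants = constants or ModelConstants()
    _check_range(relevance, "relevance", 0.0, 1.0)
    if n_target < 0:
        raise ValidationError("n_target must be >= 0")
    ids = tuple(p.id for p in predators)
    sel, det, dil, factors = [], [], [], []
    for p in predators:
        zf = focal.vulnerability.get(p.id, 0.0)
        zt = target.vulnerability.get(p.id, 0.0)
        at = target.alarm_prob.get(p.id, 0.0)
        # an empty group has no target for the predator to prefer
        l = float(target_selection_prob(zf, zt)) if n_target > 0 else zf
        x = float(
            detection_prob(
                focal.vigilance, target.vigilance, at, relevance, n_target, constants.c1
            )
        )
        y = float(dilution_prob(zf, zt, n_target))
        sel.append(l)
        det.append(x)
        dil.append(y)
        factors.append((p.pressure, l, x, y))
    d = death_prob(factors)
    k, big_k = competition_cost(
        focal.consumption,
        target.consumption,
        n_target,
        constants.c_tot,
        constants.c2,
        constants.c3,
    )
    s = float(survival(d, big_k))
    return SurvivalBreakdown(
        predators=ids,
        selection=np.array(sel),
        detection=np.array(det),
        dilution=np.array(dil),
        death=float(d),
        competition_k=float(k),
        competition=float(big_k),
        survival=s,
    )


def expected_survival(
    focal: SpeciesTraits,
    target: SpeciesTraits,
    relevance: float,
    size_distribution: Mapping[int, float],
    predators: Sequence[PredatorSpec],
    constants: ModelConstants | None = None,
) -> float:
    """Survival expectation over the target species' group-size distribution.

    ``size_distribution`` maps group sizes (target individuals, focal
    excluded) to probabilities; computed by exact enumeration over the
    support, so the result is deterministic.
    """
    sizes = list(size_distribution.keys())
    probs = np.asarray([size_distribution[n] for n in sizes], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValidationError("size_distribution must be a normalised probability mass")
    if any((not float(n).is_integer()) or n < 0 for n in sizes):
        raise ValidationError("size_distribution support must be non-negative integers")
    total = 0.0
    for n, p in zip(sizes, probs):
        if p == 0:
            continue
        total += p * scenario_breakdown(
            focal, target, relevance, int(n), predators, constants
        ).survival
    return float(total)
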