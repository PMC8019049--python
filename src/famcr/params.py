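"""Model parameters, departure model, and constraint machinery.

``ParameterSet`` gathers every probability of the family-unit model:

* ``phi[0..10]``  — annual survival of independent juveniles, subadults
  and adult females (one per alive state row of the survival matrix);
* ``s[0..3]``     — dependent-offspring survival conditional on the
  mother surviving: s1 singleton cub, s2 twin-litter cub, s3 singleton
  yearling, s4 twin-litter yearling;
* ``kappa``       — probability of first reproduction at age 5;
* ``beta[0..3]``  — breeding probability by reproductive history
  (after cub-litter loss, yearling-litter loss, successful breeding,
  previously without dependent offspring);
* ``gamma[0..3]`` — singleton-litter probability, same conditioning;
* ``p[0..10]``    — detection probability per observation class 1..11;
* ``pi[0..10]``   — initial-state proportions at first capture
  (the dead state has structural probability 0);
* ``departure``   — model for the probability that a two-year-old has
  already left its mother by the capture date.

``ConstraintMap`` expresses sharing (e.g. one phi for all states) and
fixing (e.g. kappa = 0); ``transform_parameters`` maps a constrained
ParameterSet to an unconstrained real vector (logit scale, multinomial
logit for pi) and back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit as _expit

CLIP = 1e-8

# canonical scalar parameter names, in free-vector order
PHI_NAMES = tuple(f"phi{i}" for i in range(1, 12))
S_NAMES = ("s1", "s2", "s3", "s4")
BETA_NAMES = tuple(f"beta{i}" for i in range(1, 5))
GAMMA_NAMES = tuple(f"gamma{i}" for i in range(1, 5))
P_NAMES = tuple(f"p{i}" for i in range(1, 12))
SCALAR_NAMES = PHI_NAMES + S_NAMES + ("kappa",) + BETA_NAMES + GAMMA_NAMES \
    + P_NAMES + ("alpha0",)
PI_NAMES = tuple(f"pi{i}" for i in range(1, 12))


def logit(x: float | np.ndarray) -> float | np.ndarray:
    x = np.clip(x, CLIP, 1.0 - CLIP)
    return np.log(x) - np.log1p(-x)


def expit(x: float | np.ndarray) -> float | np.ndarray:
    return _expit(x)


def _default_seasonal_coefficients() -> tuple[float, float]:
    """Logistic coefficients anchored at alpha(80)=0.40, alpha(130)=0.80.

    Two-year-olds mostly still accompany their mother at the start of the
    spring field season (day 80) and have mostly departed by its end
    (day 130); the slope/intercept are the unique solution through those
    two anchor points.
    """
    lo, hi = math.log(0.4 / 0.6), math.log(0.8 / 0.2)
    slope = (hi - lo) / (130.0 - 80.0)
    intercept = lo - slope * 80.0
    return intercept, slope


_SEAS_INTERCEPT, _SEAS_SLOPE = _default_seasonal_coefficients()


@dataclass(frozen=True)
class DepartureModel:
    """Probability that a two-year-old has departed by capture date d.

    ``kind="constant"`` uses a single rate ``alpha0``; ``kind="seasonal"``
    uses an inverse-logit of ``intercept + slope * d`` on day-of-year d.
    ``simultaneous_siblings`` forces twin two-year-olds to depart on the
    same date (the mother is then never seen with exactly one of them).
    """

    kind: str = "constant"
    alpha0: float = 0.5
    intercept: float = _SEAS_INTERCEPT
    slope: float = _SEAS_SLOPE
    simultaneous_siblings: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "seasonal"):
            raise ValueError(f"unknown departure kind {self.kind!r}")
        if self.kind == "constant" and not 0.0 <= self.alpha0 <= 1.0:
            raise ValueError("constant departure rate must be in [0, 1]")

    def probability(self, d):
        """Departure probability at day-of-year ``d`` (vectorised)."""
        d = np.asarray(d, dtype=float)
        if self.kind == "constant":
            out = np.full_like(d, self.alpha0)
        else:
            out = expit(self.intercept + self.slope * d)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ParameterSet:
    """Full probability parameterisation of the family-unit model."""

    phi: np.ndarray
    s: np.ndarray
    kappa: float
    beta: np.ndarray
    gamma: np.ndarray
    p: np.ndarray
    pi: np.ndarray
    departure: DepartureModel = field(default_factory=DepartureModel)

    def __post_init__(self) -> None:
        for name, size in (("phi", 11), ("s", 4), ("beta", 4),
                           ("gamma", 4), ("p", 11), ("pi", 11)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (size,):
                raise ValueError(f"{name} must have length {size}")
            object.__setattr__(self, name, arr)
        self.validate()

    def validate(self) -> None:
        for name in ("phi", "s", "beta", "gamma", "p", "pi"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} entries must be probabilities in [0, 1]")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1 over the 11 alive states")

    # -- named scalar access used by the constraint machinery ------------

    def get(self, name: str) -> float:
        if name in PHI_NAMES:
            return float(self.phi[PHI_NAMES.index(name)])
        if name in S_NAMES:
            return float(self.s[S_NAMES.index(name)])
        if name == "kappa":
            return float(self.kappa)
        if name in BETA_NAMES:
            return float(self.beta[BETA_NAMES.index(name)])
        if name in GAMMA_NAMES:
            return float(self.gamma[GAMMA_NAMES.index(name)])
        if name in P_NAMES:
            return float(self.p[P_NAMES.index(name)])
        if name == "alpha0":
            return float(self.departure.alpha0)
        raise KeyError(name)

    def with_values(self, values: dict[str, float],
                    pi: np.ndarray | None = None) -> "ParameterSet":
        """Return a copy with named scalars (and optionally pi) replaced."""
        phi, s, beta = self.phi.copy(), self.s.copy(), self.beta.copy()
        gamma, p = self.gamma.copy(), self.p.copy()
        kappa, dep = self.kappa, self.departure
        for name, v in values.items():
            if name in PHI_NAMES:
                phi[PHI_NAMES.index(name)] = v
            elif name in S_NAMES:
                s[S_NAMES.index(name)] = v
            elif name == "kappa":
                kappa = v
            elif name in BETA_NAMES:
                beta[BETA_NAMES.index(name)] = v
            elif name in GAMMA_NAMES:
                gamma[GAMMA_NAMES.index(name)] = v
            elif name in P_NAMES:
                p[P_NAMES.index(name)] = v
            elif name == "alpha0":
                dep = replace(dep, alpha0=v)
            else:
                raise KeyError(name)
        return ParameterSet(phi=phi, s=s, kappa=kappa, beta=beta, gamma=gamma,
                            p=p, pi=self.pi if pi is None else pi,
                            departure=dep)


def uniform_pi() -> np.ndarray:
    """Equal initial proportions over the 11 alive states."""
    return np.full(11, 1.0 / 11.0)


def default_parameters(departure: DepartureModel | None = None) -> ParameterSet:
    """A neutral mid-range ParameterSet (template / optimisation centre)."""
    return ParameterSet(
        phi=np.full(11, 0.5), s=np.full(4, 0.5), kappa=0.5,
        beta=np.full(4, 0.5), gamma=np.full(4, 0.5), p=np.full(11, 0.5),
        pi=uniform_pi(),
        departure=departure if departure is not None else DepartureModel(),
    )


@dataclass(frozen=True)
class ConstraintMap:
    """Sharing / fixing structure over the named model parameters.

    ``share`` lists groups of scalar names estimated as one free value;
    ``fix`` pins scalars to constants. Scalars not mentioned anywhere are
    individually free. ``pi_free`` controls whether the initial mixture is
    estimated (multinomial-logit, reference category pi11 = state A) or
    taken from the template ParameterSet. ``estimate_alpha0`` adds the
    constant departure rate to the free set (ignored for seasonal
    departure, whose coefficients are always taken from the template).
    """

    share: tuple[tuple[str, ...], ...] = ()
    fix: dict = field(default_factory=dict)
    pi_free: bool = True
    estimate_alpha0: bool = False

    def __post_init__(self) -> None:
        share = tuple(tuple(g) for g in self.share)
        object.__setattr__(self, "share", share)
        seen: set[str] = set()
        for g in share:
            for name in g:
                if name not in SCALAR_NAMES:
                    raise ValueError(f"unknown parameter {name!r}")
                if name in seen:
                    raise ValueError(f"parameter {name!r} in more than one group")
                seen.add(name)
        for name in self.fix:
            if name not in SCALAR_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if name in seen:
                raise ValueError(f"parameter {name!r} both shared and fixed")

    def free_groups(self) -> list[tuple[str, ...]]:
        """Free scalar groups in canonical order (pi handled separately)."""
        grouped = {n for g in self.share for n in g}
        groups: list[tuple[str, ...]] = []
        consumed: set[str] = set()
        for name in SCALAR_NAMES:
            if name == "alpha0" and not self.estimate_alpha0:
                continue
            if name in self.fix or name in consumed:
                continue
            if name in grouped:
                g = next(g for g in self.share if name in g)
                groups.append(g)
                consumed.update(g)
            else:
                groups.append((name,))
        return groups

    def group_labels(self) -> list[str]:
        """Human-readable label per free group."""
        labels = []
        for g in self.free_groups():
            labels.append(g[0] if len(g) == 1 else "=".join(g))
        return labels

    @property
    def n_free(self) -> int:
        return len(self.free_groups()) + (10 if self.pi_free else 0)


def unconstrained() -> ConstraintMap:
    """Every scalar free (alpha0 excluded unless requested)."""
    return ConstraintMap()


def scenario_constraints(departure_kind: str = "constant") -> ConstraintMap:
    """Constraints used when fitting the simulation scenarios.

    One shared survival for all independent stages, one shared detection
    probability, kappa fixed at 0 (first litter at age 6 or older). The
    constant departure rate is estimated; seasonal coefficients are
    treated as known.
    """
    return ConstraintMap(
        share=(PHI_NAMES, P_NAMES),
        fix={"kappa": 0.0},
        estimate_alpha0=(departure_kind == "constant"),
    )


def case_study_constraints() -> ConstraintMap:
    """Constraint structure of the Svalbard polar-bear analysis.

    Survival shared across states, detection shared across classes,
    breeding and singleton-litter probabilities shared between successful
    breeders and females without dependent offspring (beta3=beta4,
    gamma3=gamma4), and singleton-litter probability shared among failed
    breeders (gamma1=gamma2). kappa is estimated.
    """
    return ConstraintMap(
        share=(PHI_NAMES, P_NAMES,
               ("beta3", "beta4"), ("gamma3", "gamma4"), ("gamma1", "gamma2")),
    )


# ---------------------------------------------------------------------------
# transforms between constrained ParameterSet and free real vector


def transform_parameters(params: ParameterSet,
                         constraints: ConstraintMap) -> np.ndarray:
    """Map a ParameterSet satisfying ``constraints`` to the free vector.

    Probabilities go through the logit (clipped at 1e-8); the initial
    mixture pi through a multinomial logit with pi11 (state A) as the
    reference category. Group values are read from the first member.
    """
    for name, v in constraints.fix.items():
        if abs(params.get(name) - v) > 1e-9:
            raise ValueError(f"parameter {name} violates fixed value {v}")
    x = [logit(params.get(g[0])) for g in constraints.free_groups()]
    if constraints.pi_free:
        pi = np.clip(params.pi, CLIP, None)
        x.extend(np.log(pi[:10] / pi[10]))
    return np.asarray(x, dtype=float)


def inverse_transform(x: np.ndarray, constraints: ConstraintMap,
                      template: ParameterSet) -> ParameterSet:
    """Expand a free vector into a full ParameterSet.

    ``template`` supplies fixed values, the departure model, and pi when
    it is not estimated.
    """
    groups = constraints.free_groups()
    n_scalar = len(groups)
    expected = n_scalar + (10 if constraints.pi_free else 0)
    x = np.asarray(x, dtype=float)
    if x.shape != (expected,):
        raise ValueError(f"free vector must have length {expected}")
    values: dict[str, float] = dict(constraints.fix)
    for g, xi in zip(groups, x[:n_scalar]):
        v = float(expit(xi))
        for name in g:
            values[name] = v
    if constraints.pi_free:
        z = np.concatenate([x[n_scalar:], [0.0]])
        z -= z.max()
        pi = np.exp(z)
        pi /= pi.sum()
    else:
        pi = template.pi
    return template.with_values(values, pi=pi)
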