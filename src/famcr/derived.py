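"""Derived life-history quantities.

Litter-level survival from individual offspring survival, and the net
probability that a female starting a 3-year window alive and without
dependent offspring raises 0, 1 or 2 offspring to independence. The
closed forms follow the life-history event tree (breed in year one,
cubs survive to yearlings, yearlings survive to independence, mother
surviving throughout); an exhaustive enumeration oracle over the same
tree is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet


@dataclass(frozen=True)
class LitterSurvival:
    """Probability that at least one offspring of the litter survives."""

    l01: float  # singleton cub litter (= s1)
    l02: float  # twin cub litter
    l11: float  # singleton yearling litter (= s3)
    l12: float  # twin yearling litter


@dataclass(frozen=True)
class ThreeYearOutcome:
    """Pr(raise 0 / 1 / 2 offspring to independence in 3 years from A)."""

    pr0: float
    pr1: float
    pr2: float


def litter_survival(params: ParameterSet) -> LitterSurvival:
    """Litter survival from individual offspring survival rates.

    For twins the litter survives unless both members die:
    l = 1 - (1 - s)^2.
    """
    s1, s2, s3, s4 = params.s
    return LitterSurvival(
        l01=float(s1),
        l02=float(1.0 - (1.0 - s2) ** 2),
        l11=float(s3),
        l12=float(1.0 - (1.0 - s4) ** 2),
    )


def three_year_outcomes(params: ParameterSet) -> ThreeYearOutcome:
    """Closed-form 3-year reproductive outcome probabilities.

    The female starts in state A; breeding in year one uses the
    successful-breeder rates (beta3, gamma3), the convention of the
    constrained case-study model where beta3 = beta4 and gamma3 = gamma4.
    Adult survival uses the last (adult) entry of phi.

        Pr(X=2) = phi^3 * beta3 * (1-gamma3) * s2^2 * s4^2
        Pr(X=1) = phi^3 * beta3 * [gamma3*s1*s3
                   + (1-gamma3)*(2*s2*(1-s2)*s3 + s2^2*2*s4*(1-s4))]
        Pr(X=0) = 1 - Pr(X=1) - Pr(X=2)

    A twin litter reduced to one surviving cub continues with the
    singleton yearling rate s3.
    """
    phi = float(params.phi[10])
    b3 = float(params.beta[2])
    g3 = float(params.gamma[2])
    s1, s2, s3, s4 = (float(v) for v in params.s)
    pr2 = phi ** 3 * b3 * (1.0 - g3) * s2 ** 2 * s4 ** 2
    pr1 = phi ** 3 * b3 * (
        g3 * s1 * s3
        + (1.0 - g3) * (2.0 * s2 * (1.0 - s2) * s3
                        + s2 ** 2 * 2.0 * s4 * (1.0 - s4)))
    return ThreeYearOutcome(pr0=1.0 - pr1 - pr2, pr1=pr1, pr2=pr2)


def three_year_outcomes_oracle(params: ParameterSet) -> ThreeYearOutcome:
    """Brute-force enumeration of the 3-year life-history event tree.

    Enumerates mother survival in each of the three years, the breeding
    decision, litter size, each offspring's cub-year survival and each
    survivor's yearling-year survival, and accumulates path probabilities
    by the number of offspring reaching independence. Offspring die with
    the mother; survival rates switch to the singleton rates when a twin
    litter is reduced to one.
    """
    phi = float(params.phi[10])
    b3 = float(params.beta[2])
    g3 = float(params.gamma[2])
    s1, s2, s3, s4 = (float(v) for v in params.s)
    pr = np.zeros(3)

    def _bern(prob: float, k: int) -> float:
        return prob if k else 1.0 - prob

    for m1 in (0, 1):  # mother survives year 1?
        w1 = _bern(phi, m1)
        if not m1:
            pr[0] += w1
            continue
        for breed in (0, 1):
            wb = w1 * _bern(b3, breed)
            if not breed:
                pr[0] += wb
                continue
            for litter in (1, 2):
                wl = wb * (g3 if litter == 1 else 1.0 - g3)
                s_cub = s1 if litter == 1 else s2
                for m2 in (0, 1):  # mother survives year 2?
                    w2 = wl * _bern(phi, m2)
                    if not m2:
                        pr[0] += w2
                        continue
                    for cubs in range(litter + 1):
                        n_paths = 2 if (litter == 2 and cubs == 1) else 1
                        wc = w2 * n_paths * s_cub ** cubs \
                            * (1.0 - s_cub) ** (litter - cubs)
                        if cubs == 0:
                            pr[0] += wc
                            continue
                        s_yr = s3 if cubs == 1 else s4
                        for m3 in (0, 1):  # mother survives year 3?
                            w3 = wc * _bern(phi, m3)
                            if not m3:
                                pr[0] += w3
                                continue
                            for yr in range(cubs + 1):
                                n_paths = 2 if (cubs == 2 and yr == 1) else 1
                                wy = w3 * n_paths * s_yr ** yr \
                                    * (1.0 - s_yr) ** (cubs - yr)
                                pr[yr] += wy
    return ThreeYearOutcome(pr0=float(pr[0]), pr1=float(pr[1]),
                            pr2=float(pr[2]))
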