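"""Transition and observation matrices of the family-unit model.

The annual transition over the 12 demographic states decomposes into
four row-stochastic steps,

    Psi = Phi . Psi1 . Psi2 . Psi3,

ordering the conditioning of the life cycle: survival of the independent
female (Phi, 12x12), survival of her dependent offspring given she
survived (Psi1, 12x13), her breeding decision given the offspring
outcome (Psi2, 13x16), and litter size given she breeds (Psi3, 16x12).

The observation process likewise decomposes as E = E1 . E2: E1 (12x12)
maps the true state to what could be seen at the capture date (state
uncertainty from two-year-olds that may already have departed, at rate
alpha(d)), and E2 (12x12) applies class-specific detection.
"""

from __future__ import annotations

import numpy as np

from .params import DepartureModel, ParameterSet
from .states import (A, A01, A02, A11, A12, AS1, AS2, D, J2, J3,
                     N_OBS, N_SDPRIME, N_SPRIME, N_STATES, SA4, SA5, SPACE)

_IP = SPACE.idx_Sprime
_ID = SPACE.idx_Sdprime


def build_phi(params: ParameterSet) -> np.ndarray:
    """Survival of the independent female: S -> S, 12x12.

    Each alive state keeps its label with probability phi_i and moves to
    the absorbing dead state D otherwise; dependent offspring die with
    their mother, which is why the whole family row moves to D.
    """
    M = np.zeros((N_STATES, N_STATES))
    M[np.arange(11), np.arange(11)] = params.phi
    M[np.arange(11), D] = 1.0 - params.phi
    M[D, D] = 1.0
    return M


def build_psi1(params: ParameterSet) -> np.ndarray:
    """Offspring survival (and ageing) given mother survival: S -> S', 12x13."""
    s1, s2, s3, s4 = params.s
    k = params.kappa
    M = np.zeros((N_STATES, N_SPRIME))
    M[J2, _IP["J3"]] = 1.0
    M[J3, _IP["SA4"]] = 1.0
    M[SA4, _IP["SA5"]] = 1.0 - k
    M[SA4, _IP["A"]] = k
    M[SA5, _IP["A"]] = 1.0
    M[A01, _IP["A11"]] = s1
    M[A01, _IP["A0-"]] = 1.0 - s1
    M[A02, _IP["A11"]] = 2.0 * s2 * (1.0 - s2)
    M[A02, _IP["A12"]] = s2 ** 2
    M[A02, _IP["A0-"]] = (1.0 - s2) ** 2
    M[A11, _IP["AS1"]] = s3
    M[A11, _IP["A1-"]] = 1.0 - s3
    M[A12, _IP["AS1"]] = 2.0 * s4 * (1.0 - s4)
    M[A12, _IP["AS2"]] = s4 ** 2
    M[A12, _IP["A1-"]] = (1.0 - s4) ** 2
    M[AS1, _IP["I/AS1"]] = 1.0
    M[AS2, _IP["I/AS2"]] = 1.0
    M[A, _IP["A"]] = 1.0
    M[D, _IP["D"]] = 1.0
    return M


def build_psi2(params: ParameterSet) -> np.ndarray:
    """Breeding decision given reproductive history: S' -> S'', 13x16."""
    b1, b2, b3, b4 = params.beta
    M = np.zeros((N_SPRIME, N_SDPRIME))
    for lbl in ("J3", "SA4", "SA5", "A11", "A12", "AS1", "AS2", "D"):
        M[_IP[lbl], _ID[lbl]] = 1.0
    M[_IP["A0-"], _ID["B/A0-"]] = b1
    M[_IP["A0-"], _ID["NB/A0-"]] = 1.0 - b1
    M[_IP["A1-"], _ID["B/A1-"]] = b2
    M[_IP["A1-"], _ID["NB/A1-"]] = 1.0 - b2
    for lbl in ("I/AS1", "I/AS2"):
        M[_IP[lbl], _ID["B/AS"]] = b3
        M[_IP[lbl], _ID["NB/AS"]] = 1.0 - b3
    M[_IP["A"], _ID["B/A"]] = b4
    M[_IP["A"], _ID["NB/A"]] = 1.0 - b4
    return M


def build_psi3(params: ParameterSet) -> np.ndarray:
    """Litter size for breeders: S'' -> S at the next spring, 16x12."""
    g1, g2, g3, g4 = params.gamma
    M = np.zeros((N_SDPRIME, N_STATES))
    M[_ID["J3"], J3] = 1.0
    M[_ID["SA4"], SA4] = 1.0
    M[_ID["SA5"], SA5] = 1.0
    M[_ID["A11"], A11] = 1.0
    M[_ID["A12"], A12] = 1.0
    M[_ID["AS1"], AS1] = 1.0
    M[_ID["AS2"], AS2] = 1.0
    for lbl, g in (("B/A0-", g1), ("B/A1-", g2), ("B/AS", g3), ("B/A", g4)):
        M[_ID[lbl], A01] = g
        M[_ID[lbl], A02] = 1.0 - g
    for lbl in ("NB/A0-", "NB/A1-", "NB/AS", "NB/A"):
        M[_ID[lbl], A] = 1.0
    M[_ID["D"], D] = 1.0
    return M


def build_transition(params: ParameterSet) -> np.ndarray:
    """Annual transition Psi = Phi . Psi1 . Psi2 . Psi3 over S, 12x12."""
    return build_phi(params) @ build_psi1(params) @ build_psi2(params) \
        @ build_psi3(params)


def departure_probability(model: DepartureModel, d) -> float | np.ndarray:
    """Probability a two-year-old has departed by day-of-year ``d``."""
    return model.probability(d)


def build_e1(params: ParameterSet, d: float) -> np.ndarray:
    """Observation classes at the capture date: S -> O, 12x12.

    Only the successful-breeder states are ambiguous: each two-year-old
    has independently departed by date d with probability alpha(d), so an
    AS2 mother may be seen with two, one or zero dependent two-year-olds.
    With ``simultaneous_siblings`` both leave on the same date and the
    one-offspring class has probability zero.
    """
    a = float(departure_probability(params.departure, d))
    M = np.zeros((N_STATES, N_OBS))
    for state in (J2, J3, SA4, SA5, A01, A02, A11, A12):
        M[state, state] = 1.0  # classes 1..8 are one-to-one with states
    M[AS1, 8] = 1.0 - a
    M[AS1, 10] = a
    if params.departure.simultaneous_siblings:
        M[AS2, 9] = 1.0 - a
        M[AS2, 10] = a
    else:
        M[AS2, 8] = 2.0 * a * (1.0 - a)
        M[AS2, 9] = (1.0 - a) ** 2
        M[AS2, 10] = a ** 2
    M[A, 10] = 1.0
    M[D, 11] = 1.0
    return M


def build_e2(params: ParameterSet) -> np.ndarray:
    """Detection: observation class O -> recorded event, 12x12.

    Class k is recorded as event k with probability p_k and missed
    (event 12, code 0 on disk) otherwise; the not-captured class is
    always recorded as event 12.
    """
    M = np.zeros((N_OBS, N_OBS))
    M[np.arange(11), np.arange(11)] = params.p
    M[np.arange(11), 11] = 1.0 - params.p
    M[11, 11] = 1.0
    return M


def build_event(params: ParameterSet, d: float) -> np.ndarray:
    """Composite observation process E = E1 . E2 at capture date d."""
    return build_e1(params, d) @ build_e2(params)
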