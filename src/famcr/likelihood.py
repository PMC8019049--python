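"""Forward-algorithm likelihood for family-unit encounter histories.

The model is a hidden Markov chain over the 12 demographic states,
conditioned on first capture: the initial term combines the estimated
state mixture pi at first capture with the capture-date observation
matrix E1 (detection is excluded at the first occasion), and every later
occasion contributes a propagation through the annual transition Psi
followed by the event's emission column of E(d) = E1(d) . E2.

Occasions without a capture have no date. With detection shared across
classes the nonobservation column is exactly 1 - p for every alive state
(date-free); with class-specific detection the column is evaluated at a
configurable expected capture date (``noncapture_date``, default the
mid-season day 105).
"""

from __future__ import annotations

import logging

import numpy as np

from .data import CompiledData, Dataset, FamilyHistory
from .matrices import build_e1, build_event, build_transition, departure_probability
from .params import ParameterSet
from .states import A, AS1, AS2, event_to_index

logger = logging.getLogger(__name__)

#: Expected capture date used for nonobservation columns when detection
#: is class-specific (midpoint of the spring field season).
DEFAULT_NONCAPTURE_DATE = 105.0


def initial_event_probability(params: ParameterSet, event: int,
                              d: float) -> np.ndarray:
    """Unnormalised state vector at first capture given the first event.

    Elementwise product pi_s * E1(d)[s, class(event)]: the estimated
    initial-state mixture times the probability that state s yields the
    observed class at capture date d. Detection is excluded (the
    likelihood is conditioned on the first capture having happened).
    """
    if event == 0:
        raise ValueError("first capture cannot be a nonobservation (event 0)")
    c = event_to_index(event)
    pi_full = np.append(params.pi, 0.0)  # dead state: structural zero
    return pi_full * build_e1(params, d)[:, c]


def _initial_vectors(params: ParameterSet, cd: CompiledData) -> np.ndarray:
    """v0[h] = pi (x) E1(d_first)[., first class], detection excluded."""
    H = cd.first.shape[0]
    v0 = np.zeros((H, 12))
    dep = params.departure
    for c in range(11):
        rows = np.nonzero(cd.first_class == c)[0]
        if rows.size == 0:
            continue
        if c <= 7:
            v0[rows, c] = params.pi[c]
        else:
            a = np.asarray(departure_probability(dep, cd.first_doy[rows]))
            if c == 8:
                v0[rows, AS1] = params.pi[AS1] * (1.0 - a)
                if not dep.simultaneous_siblings:
                    v0[rows, AS2] = params.pi[AS2] * 2.0 * a * (1.0 - a)
            elif c == 9:
                one_left = (1.0 - a) if dep.simultaneous_siblings else (1.0 - a) ** 2
                v0[rows, AS2] = params.pi[AS2] * one_left
            else:  # class 11: mother seen alone
                v0[rows, AS1] = params.pi[AS1] * a
                both_gone = a if dep.simultaneous_siblings else a ** 2
                v0[rows, AS2] = params.pi[AS2] * both_gone
                v0[rows, A] = params.pi[A]
    return v0


def _emission_tensor(params: ParameterSet, cd: CompiledData,
                     noncapture_date: float) -> np.ndarray:
    """B[h, t, s] = emission probability of the event at (h, t) from state s."""
    H, T = cd.event_idx.shape
    B = np.zeros((H, T, 12))
    dep = params.departure
    for c, rows, cols, dates in cd.capture_cells:
        if rows.size == 0:
            continue
        pc = params.p[c]
        if c <= 7:
            B[rows, cols, c] = pc
        elif c == 8:
            a = np.asarray(departure_probability(dep, dates))
            B[rows, cols, AS1] = pc * (1.0 - a)
            if not dep.simultaneous_siblings:
                B[rows, cols, AS2] = pc * 2.0 * a * (1.0 - a)
        elif c == 9:
            a = np.asarray(departure_probability(dep, dates))
            one_left = (1.0 - a) if dep.simultaneous_siblings else (1.0 - a) ** 2
            B[rows, cols, AS2] = pc * one_left
        else:  # class 11
            a = np.asarray(departure_probability(dep, dates))
            B[rows, cols, AS1] = pc * a
            both_gone = a if dep.simultaneous_siblings else a ** 2
            B[rows, cols, AS2] = pc * both_gone
            B[rows, cols, A] = pc
    if cd.noncapture_rows.size:
        col0 = build_event(params, noncapture_date)[:, 11]
        B[cd.noncapture_rows, cd.noncapture_cols, :] = col0
    return B


def compiled_loglik(cd: CompiledData, params: ParameterSet,
                    noncapture_date: float = DEFAULT_NONCAPTURE_DATE
                    ) -> tuple[float, np.ndarray]:
    """Total and per-history log-likelihood on a CompiledData."""
    H, T = cd.event_idx.shape
    Psi = build_transition(params)
    B = _emission_tensor(params, cd, noncapture_date)
    v0 = _initial_vectors(params, cd)
    v = np.zeros((H, 12))
    logs = np.zeros(H)
    for t in range(T):
        if t > 0:
            # not-yet-started rows are zero and stay zero
            v = (v @ Psi) * B[:, t, :]
        rows = cd.start_rows[t]
        if rows.size:
            v[rows] = v0[rows]
        if t % 8 == 7:  # occasional rescale; float64 headroom is ample
            c = v.sum(axis=1)
            safe = c > 0.0
            logs[safe] += np.log(c[safe])
            v[safe] /= c[safe, None]
    c = v.sum(axis=1)
    ok = c > 0.0
    with np.errstate(divide="ignore"):
        logs = np.where(ok, logs + np.log(np.where(ok, c, 1.0)), -np.inf)
    if not np.all(ok):
        logger.debug("%d histories have probability 0 under the parameters",
                     int((~ok).sum()))
    return float(logs.sum()), logs


def forward_loglik(history: FamilyHistory, params: ParameterSet, T: int,
                   noncapture_date: float = DEFAULT_NONCAPTURE_DATE) -> float:
    """Log-likelihood of one family history (scaled forward algorithm).

    Returns -inf (with a logged diagnostic) if the history is impossible
    under ``params``.
    """
    cd = CompiledData(Dataset((history,), T))
    return compiled_loglik(cd, params, noncapture_date)[0]


def dataset_loglik(data: Dataset, params: ParameterSet,
                   noncapture_date: float = DEFAULT_NONCAPTURE_DATE) -> float:
    """Sum of history log-likelihoods (family units are independent)."""
    return compiled_loglik(CompiledData(data), params, noncapture_date)[0]
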