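"""Closed-form steady-state signal models for STAIR and PD acquisitions.

The STAIR cycle is: adiabatic inversion (longitudinal magnetization scaled
by the inversion efficiency q), free recovery for TI, a 90 degree
excitation that zeroes the longitudinal magnetization, readout with T2*
decay, then free recovery for the remaining TR - TI.  In the steady state
the longitudinal magnetization available at the excitation is

    Mz = m0 * (1 - q * exp(-TR/T1) - (1 - q) * exp(-TI/T1))

and the acquired signal is Mz * exp(-TE/T2*).  Signals are returned
*signed*: the null crossing of a long-T1 pool as TI varies is physically
meaningful and tests depend on it.  Magnitude is applied only by the
phantom's noise stage.

The proton-density reference scan is modelled simply as
m0 * exp(-TE/T2*) -- at a 5 degree flip angle and short TE the acquisition
is proton-density weighted and TR/flip dependence is absorbed into the
arbitrary units of m0.
"""

from __future__ import annotations

import math

from stairmwi.errors import DomainError, InvalidProtocolError
from stairmwi.params import QuantConstants, RelaxationPool, SequenceParams

__all__ = [
    "stair_steady_state_signal",
    "pd_signal",
    "mw_signal_scale",
    "steady_state_oracle",
]


def _require_stair(seq: SequenceParams) -> None:
    if seq.ti_ms is None:
        raise InvalidProtocolError("STAIR model requires an inversion time (ti_ms)")
    if seq.flip_deg != 90.0:
        raise InvalidProtocolError(
            "the steady-state STAIR model assumes a 90 degree excitation "
            f"(got flip_deg={seq.flip_deg})"
        )


def stair_steady_state_signal(pool: RelaxationPool, seq: SequenceParams) -> float:
    """Signed steady-state STAIR signal of one relaxation pool.

    Returns ``m0 * (1 - q e^{-TR/T1} - (1-q) e^{-TI/T1}) * e^{-TE/T2*}``.
    Negative values indicate a pool still recovering through its null at
    the chosen inversion time.
    """
    _require_stair(seq)
    mz = 1.0 - pool.q * math.exp(-seq.tr_ms / pool.t1_ms) \
        - (1.0 - pool.q) * math.exp(-seq.ti_ms / pool.t1_ms)
    return pool.m0 * mz * math.exp(-seq.te_ms / pool.t2s_ms)


def pd_signal(pool: RelaxationPool, seq: SequenceParams) -> float:
    """Proton-density-weighted signal: ``m0 * e^{-TE/T2*}``.

    TR and flip angle do not enter this model (see module docstring).
    """
    return pool.m0 * math.exp(-seq.te_ms / pool.t2s_ms)


def mw_signal_scale(constants: QuantConstants, seq: SequenceParams) -> float:
    """STAIR signal per unit myelin-water magnetization.

    Evaluates the STAIR steady state with the assumed myelin-water
    constants (T1, T2*, q_mw) and m0 = 1.  This is the denominator scale
    of the aMWF estimator.
    """
    pool = RelaxationPool(
        m0=1.0, t1_ms=constants.t1_mw_ms, t2s_ms=constants.t2s_mw_ms,
        q=constants.q_mw,
    )
    return stair_steady_state_signal(pool, seq)


def steady_state_oracle(
    pool: RelaxationPool, seq: SequenceParams, n_cycles: int = 200
) -> float:
    """Explicit cycle recursion converging to the STAIR steady state.

    Independent of the closed form: starting from equilibrium, each cycle
    applies the 90 degree excitation (Mz -> 0), recovers for TR - TI,
    scales Mz by q (inversion), recovers for TI, and reads out with T2*
    decay.  Returns the readout signal of the last cycle.
    """
    _require_stair(seq)
    if n_cycles < 1:
        raise DomainError(f"n_cycles must be >= 1, got {n_cycles}")
    e_rec = math.exp(-(seq.tr_ms - seq.ti_ms) / pool.t1_ms)
    e_ti = math.exp(-seq.ti_ms / pool.t1_ms)
    mz = pool.m0
    for _ in range(n_cycles):
        mz = 0.0                                   # 90 deg excitation
        mz = pool.m0 + (mz - pool.m0) * e_rec      # recover TR - TI
        mz = pool.q * mz                           # adiabatic inversion
        mz = pool.m0 + (mz - pool.m0) * e_ti       # recover TI
    return mz * math.exp(-seq.te_ms / pool.t2s_ms)
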