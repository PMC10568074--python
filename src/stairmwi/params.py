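"""Acquisition and tissue parameter containers.

All times are in milliseconds throughout the package.  Configuration
loading rejects second-scale repetition times (TR > 10000 ms) because a
mixed-unit config is the most common way to corrupt a quantitative map.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

from stairmwi.errors import DomainError, InvalidProtocolError

#: Longest repetition time accepted before we assume a unit mistake (ms).
_MAX_SANE_TR_MS = 10_000.0


@dataclass(frozen=True)
class SequenceParams:
    """Timing and geometry of one acquisition.

    Parameters
    ----------
    tr_ms : float
        Repetition time (ms), > 0.
    ti_ms : float or None
        Inversion time (ms); ``None`` for protocols without an inversion
        pulse (the proton-density reference scan).  When present it must
        satisfy ``0 < ti_ms < tr_ms``.
    te_ms : float
        Echo time (ms), >= 0.
    flip_deg : float
        Excitation flip angle in degrees, in (0, 90].
    nex : int
        Number of excitations averaged, >= 1.
    label : str
        Free-text protocol name.
    """

    tr_ms: float
    ti_ms: float | None = None
    te_ms: float = 0.0
    flip_deg: float = 90.0
    nex: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if not self.tr_ms > 0:
            raise DomainError(f"tr_ms must be > 0, got {self.tr_ms}")
        if self.tr_ms > _MAX_SANE_TR_MS:
            warnings.warn(
                f"tr_ms={self.tr_ms} looks like seconds-scale input; "
                "all times must be milliseconds",
                stacklevel=2,
            )
        if self.te_ms < 0:
            raise DomainError(f"te_ms must be >= 0, got {self.te_ms}")
        if not 0 < self.flip_deg <= 90:
            raise DomainError(f"flip_deg must be in (0, 90], got {self.flip_deg}")
        if self.nex < 1 or int(self.nex) != self.nex:
            raise DomainError(f"nex must be a positive integer, got {self.nex}")
        if self.ti_ms is not None and not 0 < self.ti_ms < self.tr_ms:
            raise InvalidProtocolError(
                f"ti_ms must satisfy 0 < TI < TR, got TI={self.ti_ms}, TR={self.tr_ms}"
            )

    def replace(self, **kw) -> "SequenceParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RelaxationPool:
    """One water compartment.

    Attributes
    ----------
    m0 : float
        Equilibrium longitudinal magnetization (arbitrary units, >= 0).
    t1_ms, t2s_ms : float
        Longitudinal and effective transverse relaxation times (ms), > 0.
    q : float
        Inversion efficiency applied by the adiabatic pulse; -1 is full
        inversion, +1 leaves the longitudinal magnetization untouched.
    """

    m0: float
    t1_ms: float
    t2s_ms: float
    q: float = -1.0

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise DomainError(f"m0 must be >= 0, got {self.m0}")
        if not self.t1_ms > 0:
            raise DomainError(f"t1_ms must be > 0, got {self.t1_ms}")
        if not self.t2s_ms > 0:
            raise DomainError(f"t2s_ms must be > 0, got {self.t2s_ms}")
        if not -1.0 <= self.q <= 1.0:
            raise DomainError(f"q must lie in [-1, 1], got {self.q}")


@dataclass(frozen=True)
class QuantConstants:
    """Fixed tissue constants assumed by the aMWF estimator.

    Myelin water is modelled with T1 = 220 ms and T2* = 10 ms; the total
    water pool decays with T2* = 60 ms.  The adiabatic pulse inverts long-T1
    water almost perfectly (q_long = -1) but only partially inverts the
    short-T2* myelin water (q_mw = -0.75).  Long-T1 suppression is designed
    over T1 in [600, 2000] ms.
    """

    t1_mw_ms: float = 220.0
    t2s_mw_ms: float = 10.0
    t2s_total_ms: float = 60.0
    q_mw: float = -0.75
    q_long: float = -1.0
    t1_suppress_lo_ms: float = 600.0
    t1_suppress_hi_ms: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("t1_mw_ms", "t2s_mw_ms", "t2s_total_ms",
                     "t1_suppress_lo_ms", "t1_suppress_hi_ms"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if not self.t1_suppress_lo_ms < self.t1_suppress_hi_ms:
            raise DomainError("t1_suppress_lo_ms must be < t1_suppress_hi_ms")
        for name in ("q_mw", "q_long"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise DomainError(f"{name} must lie in [-1, 1]")

    def replace(self, **kw) -> "QuantConstants":
        return dataclasses.replace(self, **kw)


#: STAIR-EPI protocol used throughout: TR/TI/TE = 250/117/5.5 ms, 90deg
#: excitation, 30 averages.
STAIR_PROTOCOL = SequenceParams(
    tr_ms=250.0, ti_ms=117.0, te_ms=5.5, flip_deg=90.0, nex=30, label="STAIR-EPI"
)

#: Proton-density reference protocol: TR/TE = 250/5.5 ms, 5deg excitation,
#: 10 averages.  The PD signal model ignores TR and flip angle.
PD_PROTOCOL = SequenceParams(
    tr_ms=250.0, ti_ms=None, te_ms=5.5, flip_deg=5.0, nex=10, label="PD-EPI"
)
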