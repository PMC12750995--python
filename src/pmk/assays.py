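"""Reduction of equilibrium-dialysis and Caco-2 transport raw data.

Equilibrium dialysis against a cell homogenate yields the unbound fraction
fu = C_buffer / C_homogenate and the bound-to-unbound ratio
Cb/Cu = (C_homogenate - C_buffer) / C_buffer; buffer readings below the
lower limit of quantification are imputed at LLOQ/2.  Transepithelial
transport time-courses reduce to the apparent permeability
Papp = (dQ/dt) / (A * D) with the cumulative receiver amount corrected for
withdrawn-and-replaced samples, and to the 0-120 min mass recovery
recovery(%) = 100 * (CR120*VR + CR45*0.1 + CD45*0.01 + CD120*VD) / (D0*VD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientTimepoints,
    MissingVolumes,
    NegativeConcentration,
    NonPositiveDonor,
    ZeroHomogenate,
)

__all__ = [
    "DialysisMeasurement",
    "BindingResult",
    "TransportExperiment",
    "PappResult",
    "RecoveryResult",
    "binding_from_dialysis",
    "papp",
    "recovery",
    "mass_balance",
]


@dataclass
class DialysisMeasurement:
    """One dialysis replicate; concentrations in uM, LLOQ in uM."""

    c_homogenate: float
    c_buffer: float
    lloq: float
    replicate: str = ""
    nominal_conc: float = 0.1  # uM, assay standard concentration
    v_homogenate_ml: float = 0.2
    v_buffer_ml: float = 0.35


@dataclass
class BindingResult:
    fu: float
    cb_over_cu: float
    log_cb_over_cu: float  # log10; NaN when the ratio is 0
    lloq_imputed: bool
    degenerate: bool = False  # c_buffer == c_homogenate (ratio 0)


@dataclass
class TransportExperiment:
    """A-B transport time-course for one compound.

    Concentrations in uM (= nmol/mL); volumes in mL; times in minutes; the
    insert area in cm^2.  ``receiver_conc`` aligns with ``times_min``;
    receiver withdrawals of ``v_withdraw_ml`` at each sampled time are
    replaced with fresh buffer.  ``donor_conc`` optionally holds the donor
    samples at the same times (first entry defines D0 if ``d0`` is not set).
    """

    times_min: Sequence[float]
    receiver_conc: Sequence[float]
    d0: float = 10.0
    donor_conc: Sequence[float] | None = None
    v_donor_ml: float = 0.2
    v_receiver_ml: float = 0.8
    v_withdraw_ml: float = 0.1
    v_donor_sample_ml: float = 0.01
    area_cm2: float = 0.33

    def __post_init__(self) -> None:
        t = list(self.times_min)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if min(self.v_donor_ml, self.v_receiver_ml, self.area_cm2) <= 0:
            raise ValueError("volumes and area must be positive")


@dataclass
class PappResult:
    papp: float  # cm/s
    slope: float  # nmol/s
    q_corrected: np.ndarray = field(default_factory=lambda: np.array([]))
    below_loq_flag: bool = False


@dataclass
class RecoveryResult:
    recovery_percent: float


def binding_from_dialysis(m: DialysisMeasurement) -> BindingResult:
    """fu, Cb/Cu and log10(Cb/Cu) with the LLOQ/2 imputation rule.

    A buffer concentration below the LLOQ is replaced by LLOQ/2 before the
    ratios are formed, and the result is flagged as imputed.
    """
    if m.c_homogenate < 0 or m.c_buffer < 0:
        raise NegativeConcentration("concentrations must be non-negative")
    if m.c_homogenate == 0:
        raise ZeroHomogenate("homogenate concentration must be positive")
    cb = m.c_buffer
    imputed = False
    if cb < m.lloq:
        cb = m.lloq / 2.0
        imputed = True
    fu = cb / m.c_homogenate
    ratio = (m.c_homogenate - cb) / cb
    degenerate = ratio <= 0
    log_ratio = math.log10(ratio) if ratio > 0 else float("nan")
    return BindingResult(
        fu=fu,
        cb_over_cu=max(ratio, 0.0),
        log_cb_over_cu=log_ratio,
        lloq_imputed=imputed,
        degenerate=degenerate,
    )


def cumulative_receiver_amount(exp: TransportExperiment) -> np.ndarray:
    """Withdrawal-corrected cumulative receiver amount Q (nmol) per time.

    Q(t_k) = C_R(t_k) * V_R + sum_{j<k} C_R(t_j) * V_withdraw, restoring the
    amounts removed by earlier replaced samples.
    """
    cr = np.asarray(exp.receiver_conc, dtype=float)
    q = cr * exp.v_receiver_ml
    q += np.concatenate(([0.0], np.cumsum(cr[:-1]))) * exp.v_withdraw_ml
    return q


def papp(
    exp: TransportExperiment,
    include_origin: bool = True,
    donor_mode: str = "initial",
) -> PappResult:
    """Apparent permeability Papp = (dQ/dt) / (A * D) in cm/s.

    dQ/dt is the least-squares slope of the withdrawal-corrected cumulative
    receiver amount against time; D is the initial donor concentration by
    default (``donor_mode="mean"`` uses the time-averaged donor samples).
    ``include_origin`` prepends (t=0, Q=0) to the fit.
    """
    if exp.d0 <= 0:
        raise NonPositiveDonor("donor concentration must be positive")
    q = cumulative_receiver_amount(exp)
    t = np.asarray(exp.times_min, dtype=float) * 60.0  # -> seconds
    if include_origin and (t.size == 0 or t[0] > 0):
        t = np.concatenate(([0.0], t))
        q = np.concatenate(([0.0], q))
    if t.size < 2:
        raise InsufficientTimepoints("need at least two receiver time points")
    slope = float(np.polyfit(t, q, 1)[0])  # nmol/s
    if donor_mode == "initial":
        donor = exp.d0
    elif donor_mode == "mean":
        if not exp.donor_conc:
            raise NonPositiveDonor("donor_mode='mean' requires donor samples")
        donor = float(np.mean(exp.donor_conc))
    else:
        raise ValueError(f"unknown donor_mode {donor_mode!r}")
    return PappResult(
        papp=max(slope, 0.0) / (exp.area_cm2 * donor),
        slope=slope,
        q_corrected=q,
    )


def recovery(
    exp: TransportExperiment,
    cd45: float,
    cd120: float,
    cr45: float | None = None,
    cr120: float | None = None,
) -> RecoveryResult:
    """0-120 min mass recovery in percent.

    recovery(%) = 100 * (CR120*VR + CR45*v_withdraw + CD45*v_donor_sample +
    CD120*VD) / (D0*VD), with the printed sampling volumes (0.1 and 0.01 mL)
    as configurable defaults on the experiment.
    """
    if exp.d0 <= 0:
        raise NonPositiveDonor("D0 must be positive")
    cr = dict(zip(exp.times_min, exp.receiver_conc))
    if cr45 is None:
        cr45 = cr.get(45.0, cr.get(45, 0.0))
    if cr120 is None:
        cr120 = cr.get(120.0, cr.get(120, 0.0))
    total = (
        cr120 * exp.v_receiver_ml
        + cr45 * exp.v_withdraw_ml
        + cd45 * exp.v_donor_sample_ml
        + cd120 * exp.v_donor_ml
    )
    return RecoveryResult(100.0 * total / (exp.d0 * exp.v_donor_ml))


def mass_balance(
    c_homogenate_final: float,
    c_buffer_final: float,
    nominal_conc: float,
    v_homogenate_ml: float | None = 0.2,
    v_buffer_ml: float | None = 0.35,
) -> float:
    """Dialysis mass balance: percent of the nominal amount recovered from
    both chambers at the end of the experiment."""
    if v_homogenate_ml is None or v_buffer_ml is None:
        raise MissingVolumes("chamber volumes are required")
    recovered = c_homogenate_final * v_homogenate_ml + c_buffer_final * v_buffer_ml
    nominal = nominal_conc * v_homogenate_ml
    return 100.0 * recovered / nominal
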