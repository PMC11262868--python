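"""Threshold-LQ survival and the two-branch RBE dose response.

Cell survival follows a linear-quadratic (LQ) curve up to a threshold dose
D_t and a pure log-linear tail above it:

    S(D) = exp[-(a0 + b z*) D - b D^2]                    for D <= D_t
         = S_LQ(D_t) exp[-a_t (D - D_t)]                  for D >  D_t
    a_t  = (a0 + b z*) + 2 b D_t

so that log S and its slope are continuous at D_t.  The intrinsic linear
coefficient a0 is eliminated through a clinically evaluated alpha/beta
ratio, a0/b = (alpha/beta)_c - z*_c, where z*_c belongs to a typical
clinical field.  Equating survival between a test and a reference field
then yields an RBE that depends only on dose and the three
saturation-corrected specific energies — the quadratic coefficient b
cancels.  Writing A_x = (alpha/beta)_c - z*_c + z*_x:

    RBE_LQ(D) = [A_test + sqrt(A_test^2 + 4 (A_ref + D) D)] / [2 (A_ref + D)]
                                                           for D <= D_t
    RBE_L(D)  = D / [ (A_ref + 2 D_t) / (A_test + 2 D_t / RBE_LQ(D_t))
                      * (D - D_t) + D_t / RBE_LQ(D_t) ]    for D >  D_t

RBE is a function of the *reference*-radiation dose D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MKParameters",
    "FieldTriplet",
    "alpha0_over_beta",
    "survival",
    "rbe",
]


@dataclass(frozen=True)
class MKParameters:
    """Tissue-level model constants plus the fitted domain radius.

    y0 : saturation parameter, keV/um (default 100)
    d_t : threshold dose, Gy (default 7)
    alpha_beta_clinical : (alpha/beta)_c of the clinical field, Gy (default 10)
    r_d : domain radius, um (None until fitted)
    """

    y0: float = 100.0
    d_t: float = 7.0
    alpha_beta_clinical: float = 10.0
    r_d: float | None = None

    def __post_init__(self) -> None:
        if self.y0 <= 0 or self.d_t <= 0 or self.alpha_beta_clinical <= 0:
            raise ValueError("y0, d_t and alpha_beta_clinical must be > 0")
        if self.r_d is not None and self.r_d <= 0:
            raise ValueError("r_d must be > 0 when set")

    def with_r_d(self, r_d: float) -> "MKParameters":
        return MKParameters(self.y0, self.d_t, self.alpha_beta_clinical, r_d)


@dataclass(frozen=True)
class FieldTriplet:
    """Saturation-corrected specific energies (Gy) of one experimental setup:
    test field, reference field, and the typical clinical field."""

    z_test: float
    z_ref: float
    z_clin: float

    def __post_init__(self) -> None:
        if self.z_test < 0 or self.z_ref < 0 or self.z_clin < 0:
            raise ValueError("specific energies must be >= 0")

    def a_test(self, alpha_beta_clinical: float) -> float:
        return alpha_beta_clinical - self.z_clin + self.z_test

    def a_ref(self, alpha_beta_clinical: float) -> float:
        return alpha_beta_clinical - self.z_clin + self.z_ref


def alpha0_over_beta(params: MKParameters, z_clin: float) -> float:
    """a0/b = (alpha/beta)_c - z*_c (Gy); warns when non-positive."""
    value = params.alpha_beta_clinical - z_clin
    if value <= 0.0:
        warnings.warn(
            f"alpha0/beta = {value:.6g} Gy is non-positive; the clinical-field "
            "z*_c exceeds (alpha/beta)_c — downstream guards may reject fields",
            stacklevel=2,
        )
    return value


def survival(
    D,
    z: float,
    params: MKParameters,
    z_clin: float,
    beta: float,
):
    """Surviving fraction at absorbed dose D (Gy) in a field with z* = z.

    ``beta`` (Gy^-2) sets the absolute scale of the exponent; RBE does not
    depend on it, so no default is shipped.  Accepts scalar or array D.
    """
    if beta <= 0.0:
        raise ValueError("beta must be > 0")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0.0):
        raise ValueError("dose must be >= 0")
    alpha0 = beta * alpha0_over_beta(params, z_clin)
    lin = alpha0 + beta * z
    if lin < 0.0:
        raise ValueError("net linear coefficient negative — check z*_c")
    log_s_lq = -(lin * D + beta * D**2)
    alpha_t = lin + 2.0 * beta * params.d_t
    log_s_at_dt = -(lin * params.d_t + beta * params.d_t**2)
    log_s_tail = log_s_at_dt - alpha_t * (D - params.d_t)
    out = np.exp(np.where(D <= params.d_t, log_s_lq, log_s_tail))
    return out if out.ndim else float(out)


def _rbe_lq(D: np.ndarray, a_test: float, a_ref: float) -> np.ndarray:
    return (a_test + np.sqrt(a_test**2 + 4.0 * (a_ref + D) * D)) / (
        2.0 * (a_ref + D)
    )


def rbe(D, fields: FieldTriplet, params: MKParameters):
    """RBE of the test field at reference-radiation dose D (Gy).

    Implements both branches; doses at or below the threshold D_t use the
    LQ branch (closed interval).  Accepts scalar or array D > 0.
    """
    a_test = fields.a_test(params.alpha_beta_clinical)
    a_ref = fields.a_ref(params.alpha_beta_clinical)
    if a_test <= 0.0 or a_ref <= 0.0:
        raise ValueError(
            f"(alpha/beta)_c - z*_c + z* must be > 0 (got A_test={a_test:.6g}, "
            f"A_ref={a_ref:.6g}); check z*_c"
        )
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0.0):
        raise ValueError("reference dose must be > 0")
    d_t = params.d_t
    lq = _rbe_lq(D, a_test, a_ref)
    rbe_at_dt = float(_rbe_lq(np.asarray(d_t), a_test, a_ref))
    slope = (a_ref + 2.0 * d_t) / (a_test + 2.0 * d_t / rbe_at_dt)
    tail = D / (slope * (D - d_t) + d_t / rbe_at_dt)
    out = np.where(D <= d_t, lq, tail)
    return out if out.ndim else float(out)
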