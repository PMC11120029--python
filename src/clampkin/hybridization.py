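"""Equilibrium duplex formation and oxoG-clamp fluorescence quenching.

The clamp-bearing strand is bright when single-stranded; pairing with an
oxoG-containing partner quenches a fraction ``quench_eff`` of its emission
(static two-state mixture: bound = partially dark, free = bright).  Pairing
with a normal-G partner does not quench at all, which is the experimental
control.  Buffer and ionic-strength effects are absorbed into Kd and
quench_eff rather than modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "QuenchModel",
    "IdentifiabilityWarning",
    "fraction_duplex",
    "predict_relative_fluorescence",
    "fit_quench_titration",
]


class IdentifiabilityWarning(UserWarning):
    """Fit parameters are weakly separable for the given design."""


@dataclass
class QuenchModel:
    """Two-component binding with static quenching.

    Kd: duplex dissociation constant (M).  quench_eff: fraction of clamp
    fluorescence lost on pairing with oxoG (0 for a G partner).  f0:
    unquenched fluorescence (a.u.); relative signals divide it out.
    """

    Kd: float
    quench_eff: float
    f0: float = 1.0
    Kd_stderr: float | None = None
    quench_eff_stderr: float | None = None
    kd_is_lower_bound: bool = False

    def __post_init__(self):
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if not 0.0 <= self.quench_eff <= 1.0:
            raise ValueError("quench_eff must lie in [0, 1]")


def fraction_duplex(clamp_total, partner_total, Kd):
    """Fraction of the clamp strand bound in duplex at equilibrium.

    Exact root of the two-component binding quadratic, written in the
    numerically stable form D = 2AB / (A + B + Kd + sqrt((A+B+Kd)^2 - 4AB))
    so that Kd << totals does not lose precision to cancellation.
    Accepts scalars or arrays for ``partner_total``.
    """
    A = float(clamp_total)
    B = np.asarray(partner_total, dtype=float)
    if A < 0 or np.any(B < 0):
        raise ValueError("concentrations must be non-negative")
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if A == 0:
        return np.zeros_like(B) if B.ndim else 0.0
    s = A + B + Kd
    duplex = 2.0 * A * B / (s + np.sqrt(s * s - 4.0 * A * B))
    frac = duplex / A
    return float(frac) if frac.ndim == 0 else frac


def predict_relative_fluorescence(model, clamp_total, partner_total, partner_is_oxoG=True):
    """Relative clamp fluorescence after adding a partner strand.

    1 - quench_eff * fraction_duplex for an oxoG partner; identically 1 for a
    normal-G partner (no quenching regardless of binding).
    """
    B = np.asarray(partner_total, dtype=float)
    if not partner_is_oxoG:
        return np.ones_like(B) if B.ndim else 1.0
    return 1.0 - model.quench_eff * fraction_duplex(clamp_total, partner_total, model.Kd)


def fit_quench_titration(
    partner_totals,
    relative_fluorescence,
    clamp_total,
    fix_Kd: float | None = None,
    fix_quench_eff: float | None = None,
    Kd_guess: float = 1e-7,
    quench_guess: float = 0.2,
) -> QuenchModel:
    """Least-squares fit of a titration series to the quench model.

    Needs >= 4 points spanning sub- to super-equimolar partner amounts.  When
    every point is saturating (bound fraction > 0.95 at the initial Kd) the
    two parameters are nearly collinear; a warning is emitted and the fitted
    Kd is flagged as a lower bound only.
    """
    B = np.asarray(partner_totals, dtype=float)
    y = np.asarray(relative_fluorescence, dtype=float)
    if B.shape != y.shape or B.size < 4:
        raise ValueError("need >= 4 matched titration points")

    nonzero = B[B > 0]
    saturated = (
        nonzero.size > 0
        and np.min(fraction_duplex(clamp_total, nonzero, fix_Kd or Kd_guess)) > 0.95
    )
    if saturated and fix_Kd is None:
        warnings.warn(
            "all titration points are saturating: Kd and quench_eff are weakly "
            "separable; fitted Kd is a lower bound only",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    def unpack(p):
        i = 0
        if fix_Kd is None:
            Kd = 10.0 ** p[i]
            i += 1
        else:
            Kd = fix_Kd
        Q = p[i] if fix_quench_eff is None else fix_quench_eff
        return Kd, Q

    def resid(p):
        Kd, Q = unpack(p)
        return 1.0 - Q * fraction_duplex(clamp_total, B, Kd) - y

    p0, lo, hi = [], [], []
    if fix_Kd is None:
        p0.append(np.log10(Kd_guess)); lo.append(-12.0); hi.append(0.0)
    if fix_quench_eff is None:
        p0.append(quench_guess); lo.append(0.0); hi.append(1.0)
    if not p0:
        raise ValueError("at least one of Kd, quench_eff must be free")

    fit = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    Kd, Q = unpack(fit.x)

    # asymptotic standard errors from the Jacobian at the optimum
    ses = [None] * len(fit.x)
    dof = y.size - len(fit.x)
    if dof > 0:
        try:
            cov = np.linalg.inv(fit.jac.T @ fit.jac) * (2 * fit.cost / dof)
            ses = list(np.sqrt(np.clip(np.diag(cov), 0, None)))
        except np.linalg.LinAlgError:
            pass
    i = 0
    Kd_se = None
    if fix_Kd is None:
        Kd_se = None if ses[i] is None else Kd * np.log(10) * ses[i]
        i += 1
    Q_se = None if (fix_quench_eff is not None or ses[i] is None) else ses[i]

    return QuenchModel(
        Kd=Kd,
        quench_eff=Q,
        Kd_stderr=Kd_se,
        quench_eff_stderr=Q_se,
        kd_is_lower_bound=saturated and fix_Kd is None,
    )
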