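"""Michaelis-Menten nonlinear fitting and activity-unit arithmetic.

The fit is unweighted least squares on untransformed rates (no
Lineweaver-Burk linearization): v = Vmax * S / (Km + S).  Initialization
follows the usual practice: Vmax0 = max(v), Km0 = the substrate
concentration whose rate is closest to Vmax0 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

from .simulate import KineticsDataset


class KineticsFitError(RuntimeError):
    """Raised on non-convergence or a physically inadmissible estimate."""

    def __init__(self, message: str, last_iterate: Optional[np.ndarray] = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class MMFit:
    """Michaelis-Menten fit result.

    ``km`` in the units of S (mg/mL here), ``vmax`` in rate units, ``kcat``
    = Vmax / E0 when the enzyme amount is known (else None).  Standard
    errors come from the Gauss-Newton covariance at the optimum.
    ``ill_conditioned`` flags fits where Km is effectively unidentifiable
    (e.g. saturated-only data).
    """

    km: float
    vmax: float
    kcat: Optional[float]
    km_se: float
    vmax_se: float
    n_obs: int
    rss: float
    ill_conditioned: bool = False


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(
    data: Union[KineticsDataset, tuple[np.ndarray, np.ndarray]],
    e0: Optional[float] = None,
) -> MMFit:
    """Fit v = Vmax*S/(Km+S) by unweighted nonlinear least squares.

    Accepts a simulated :class:`KineticsDataset` (its known E0 is used for
    kcat) or an ``(S, v)`` pair with E0 passed separately.  Requires at
    least four distinct substrate concentrations.
    """
    if isinstance(data, KineticsDataset):
        s = data.data["S"].to_numpy(dtype=float)
        v = data.data["v"].to_numpy(dtype=float)
        if e0 is None:
            e0 = data.e0
    else:
        s, v = (np.asarray(x, dtype=float) for x in data)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("S and v must be 1-D arrays of equal length")
    if np.unique(s).size < 4:
        raise KineticsFitError("need at least 4 distinct substrate concentrations")
    if (s <= 0).any():
        raise KineticsFitError("substrate concentrations must be positive")

    vmax0 = float(v.max())
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    x0 = np.array([vmax0, max(km0, 1e-12)])

    def resid(p: np.ndarray) -> np.ndarray:
        return michaelis_menten(s, p[0], p[1]) - v

    res = least_squares(
        resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=500
    )
    if not res.success:
        raise KineticsFitError(f"fit did not converge: {res.message}", res.x)
    vmax, km = res.x
    if vmax <= 0 or km <= 0:
        raise KineticsFitError(
            f"inadmissible estimate (Vmax={vmax:.4g}, Km={km:.4g}): model misfit",
            res.x,
        )

    # Gauss-Newton covariance; near-singular J means Km is unidentifiable
    jac = res.jac
    dof = max(s.size - 2, 1)
    sigma2 = 2.0 * res.cost / dof
    jtj = jac.T @ jac
    ill = False
    try:
        cov = np.linalg.inv(jtj) * sigma2
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        vmax_se, km_se = float(ses[0]), float(ses[1])
        if not np.isfinite(ses).all():
            ill = True
    except np.linalg.LinAlgError:
        vmax_se = km_se = float("inf")
        ill = True
    if np.linalg.cond(jtj) > 1e10 or (km_se > 0 and km_se / km > 10):
        ill = True
    # Km outside the sampled concentration range is not identifiable: all
    # observations sit on the saturated (or the linear) limb of the curve
    if km < 1e-2 * s.min() or km > 1e2 * s.max():
        ill = True

    return MMFit(
        km=float(km),
        vmax=float(vmax),
        kcat=(float(vmax) / e0 if e0 else None),
        km_se=km_se,
        vmax_se=vmax_se,
        n_obs=int(s.size),
        rss=float(2.0 * res.cost),
        ill_conditioned=ill,
    )


def specific_activity(product_umol: float, minutes: float, enzyme_mg: float) -> float:
    """Specific activity in U/mg: 1 U releases 1 umol product per minute."""
    if min(product_umol, minutes, enzyme_mg) <= 0:
        raise ValueError("product amount, time and enzyme mass must be positive")
    return product_umol / minutes / enzyme_mg
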