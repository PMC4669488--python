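"""Michaelis–Menten kinetics for tolbutamide 4-hydroxylation.

Each liver's microsomal tolbutamide series (seven substrate concentrations,
31.25–2000 µM, two-fold dilutions) is fit to the single-enzyme
Michaelis–Menten model

    v = Vmax * C / (Km + C)

by Levenberg–Marquardt nonlinear least squares, initialized from the
Lineweaver–Burk linearization.  The in vitro intrinsic clearance is the
low-concentration limit of v/C:

    CL_int,in vitro = Vmax / Km

with Vmax in pmol/min/mg microsomal protein and Km in µM, so that CL_int
comes out in µL/min/mg exactly (pmol/min/mg ÷ pmol/µL = µL/min/mg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TOLBUTAMIDE_GRID_UM",
    "KineticParams",
    "FitError",
    "michaelis_menten",
    "fit_michaelis_menten",
    "compute_clint_vitro",
    "fit_all",
]

#: Default tolbutamide concentration grid (µM): two-fold dilution series.
TOLBUTAMIDE_GRID_UM: tuple[float, ...] = (31.25, 62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)

# Relative tolerance on parameter change / cost used by the optimizer.
_FIT_TOL = 1e-10
_MAX_NFEV = 2000
# Parameter correlation beyond which the (Vmax, Km) pair is reported as
# practically unidentifiable (all concentrations far below Km collapse the
# model onto the one-parameter line v = (Vmax/Km)*C).
_ILL_CONDITIONED_CORR = 0.999


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the initial values and residuals."""

    def __init__(self, message: str, p0=None, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


@dataclass(frozen=True)
class KineticParams:
    """Fitted Michaelis–Menten parameters for one donor.

    vmax: pmol/min/mg microsomal protein; km: µM;
    clint_vitro = vmax/km in µL/min/mg.
    """

    donor_id: str
    vmax: float
    km: float
    clint_vitro: float
    rss: float
    converged: bool
    ill_conditioned: bool = False

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError(
                f"donor {self.donor_id}: vmax and km must be positive "
                f"(got vmax={self.vmax}, km={self.km})"
            )


def michaelis_menten(conc, vmax: float, km: float):
    """Reaction rate v = Vmax*C/(Km+C) for concentration(s) ``conc``."""
    conc = np.asarray(conc, dtype=float)
    return vmax * conc / (km + conc)


def _lineweaver_burk_init(conc: np.ndarray, rates: np.ndarray) -> tuple[float, float]:
    """Initial (Vmax, Km) from the double-reciprocal regression 1/v on 1/C."""
    pos = rates > 0
    if pos.sum() >= 2:
        res = stats.linregress(1.0 / conc[pos], 1.0 / rates[pos])
        if res.intercept > 0 and res.slope > 0:
            vmax0 = 1.0 / res.intercept
            km0 = res.slope * vmax0
            return vmax0, km0
    # fallback for degenerate reciprocal fits
    return float(rates.max()) * 1.2, float(np.median(conc))


def fit_michaelis_menten(series, weighting: str = "relative") -> KineticParams:
    """Fit Vmax and Km to one concentration–rate series.

    ``series`` is any object with ``concentrations`` (µM), ``rates``
    (pmol/min/mg) and ``donor_id`` attributes (e.g. a
    :class:`~hepscale.cohort.KineticSeries`).

    ``weighting="relative"`` (default) minimizes relative residuals
    (σ_i ∝ v_i), matching the roughly constant coefficient of variation of
    metabolite quantification across the rate range; ``"none"`` minimizes
    raw residuals, which lets the high-rate plateau points dominate and
    degrades Km precision.

    Raises
    ------
    ValueError
        Fewer than 3 distinct concentrations, or rates all zero.
    FitError
        Optimizer failure or a non-positive parameter at the optimum.
    """
    if weighting not in ("relative", "none"):
        raise ValueError(f"weighting must be 'relative' or 'none', got {weighting!r}")
    conc = np.asarray(series.concentrations, dtype=float)
    rates = np.asarray(series.rates, dtype=float)
    donor_id = getattr(series, "donor_id", "?")
    if len(np.unique(conc)) < 3:
        raise ValueError(f"donor {donor_id}: need >= 3 distinct concentrations")
    if not np.any(rates > 0):
        raise ValueError(f"donor {donor_id}: all rates are zero")

    sigma = None
    if weighting == "relative":
        # zero rates get the smallest positive rate's weight
        sigma = np.where(rates > 0, rates, rates[rates > 0].min())
    p0 = _lineweaver_burk_init(conc, rates)
    try:
        popt, pcov, info, msg, ier = optimize.curve_fit(
            michaelis_menten, conc, rates, p0=p0, sigma=sigma,
            method="lm", maxfev=_MAX_NFEV, xtol=_FIT_TOL, ftol=_FIT_TOL,
            full_output=True,
        )
    except RuntimeError as exc:  # curve_fit raises on maxfev exhaustion
        raise FitError(
            f"donor {donor_id}: Michaelis-Menten fit did not converge ({exc})",
            p0=p0,
        ) from exc
    residuals = rates - michaelis_menten(conc, *popt)
    if ier not in (1, 2, 3, 4):
        raise FitError(
            f"donor {donor_id}: optimizer reported failure ({msg})",
            p0=p0, residuals=residuals,
        )
    vmax, km = float(popt[0]), float(popt[1])
    if vmax <= 0 or km <= 0:
        raise FitError(
            f"donor {donor_id}: non-positive parameter at optimum "
            f"(vmax={vmax:.4g}, km={km:.4g})",
            p0=p0, residuals=residuals,
        )
    ill = False
    with np.errstate(invalid="ignore", divide="ignore"):
        if not np.all(np.isfinite(pcov)):
            ill = True
        else:
            denom = np.sqrt(pcov[0, 0] * pcov[1, 1])
            if denom > 0 and abs(pcov[0, 1] / denom) > _ILL_CONDITIONED_CORR:
                ill = True
    return KineticParams(
        donor_id=donor_id, vmax=vmax, km=km, clint_vitro=vmax / km,
        rss=float(residuals @ residuals), converged=True, ill_conditioned=ill,
    )


def compute_clint_vitro(params: KineticParams) -> float:
    """In vitro intrinsic clearance Vmax/Km in µL/min/mg."""
    if params.km == 0:
        raise ZeroDivisionError(f"donor {params.donor_id}: km is zero")
    return params.vmax / params.km


def fit_all(kinetics_table) -> "pandas.DataFrame":
    """Fit every donor in a tidy (donor_id, concentration_uM, rate_pmol_min_mg) table."""
    import pandas as pd
    from .cohort import KineticSeries

    rows = []
    for donor_id, grp in kinetics_table.groupby("donor_id", sort=True):
        grp = grp.sort_values("concentration_uM")
        series = KineticSeries(
            donor_id=str(donor_id),
            concentrations=grp["concentration_uM"].to_numpy(),
            rates=grp["rate_pmol_min_mg"].to_numpy(),
        )
        p = fit_michaelis_menten(series)
        rows.append(
            {
                "donor_id": p.donor_id,
                "vmax_pmol_min_mg": p.vmax,
                "km_uM": p.km,
                "clint_vitro_ul_min_mg": p.clint_vitro,
                "rss": p.rss,
                "converged": p.converged,
                "ill_conditioned": p.ill_conditioned,
            }
        )
    return pd.DataFrame(rows)
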