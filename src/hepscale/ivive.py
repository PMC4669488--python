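"""Well-stirred hepatic clearance prediction under parameter-combination methods A–G.

The extrapolation chain for each liver:

    LV [mL] = 12.5 · BW [kg] + 536.4          (liver volume, Chinese adults)
    LW [g]  = 1.001 · LV                      (liver density 1.001 g/mL)
    Q_H [mL/min] = 0.245 · CO [L/min] · 1000  (hepatic flow, 24.5% of cardiac output)

    CL_int,liver [mL/min/kg] = CL_int,in vitro [µL/min/mg] · MPPGL [mg/g]
                               · LW [g] / BW [kg] / 1000

    CL_H = Q_H · fub · CL_int,liver / (Q_H + fub · CL_int,liver)   (well-stirred)

with Q_H expressed per kg body weight so every clearance is in mL/min/kg.

Five parameters vary between donors: MPPGL, CL_int,in vitro, LW, Q_H and
BW.  Method A uses each donor's own value of all five; methods B–F
individualize exactly one (MPPGL, CL_int, LW, Q_H, BW respectively) and fix
the remaining four at the cohort arithmetic means; method G uses cohort
means throughout, collapsing to a single prediction.  Comparing the spread
of predictions across methods attributes the population variability in
CL_H to individual parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LIVER_DENSITY_G_PER_ML",
    "LIVER_VOLUME_SLOPE_ML_PER_KG",
    "LIVER_VOLUME_INTERCEPT_ML",
    "HEPATIC_FLOW_FRACTION",
    "FUB_TOLBUTAMIDE",
    "METHODS",
    "METHOD_MASKS",
    "PhysiologyParams",
    "liver_weight",
    "clint_liver",
    "well_stirred_clh",
    "predict_cohort",
]

LIVER_DENSITY_G_PER_ML = 1.001
LIVER_VOLUME_SLOPE_ML_PER_KG = 12.5
LIVER_VOLUME_INTERCEPT_ML = 536.4
#: Hepatic blood flow as a fraction of cardiac output.
HEPATIC_FLOW_FRACTION = 0.245
#: Fraction of tolbutamide unbound in blood (literature value).
FUB_TOLBUTAMIDE = 0.0982

METHODS = ("A", "B", "C", "D", "E", "F", "G")

#: Which of the five parameters each method individualizes; the rest are
#: fixed at cohort means.
METHOD_MASKS: dict[str, frozenset[str]] = {
    "A": frozenset({"mppgl", "clint_vitro", "lw", "qh", "bw"}),
    "B": frozenset({"mppgl"}),
    "C": frozenset({"clint_vitro"}),
    "D": frozenset({"lw"}),
    "E": frozenset({"qh"}),
    "F": frozenset({"bw"}),
    "G": frozenset(),
}

_PARAMS = ("mppgl", "clint_vitro", "lw", "qh", "bw")


@dataclass(frozen=True)
class PhysiologyParams:
    """Physiological inputs for one donor, derived quantities included.

    bw: kg; lv: mL; lw: g; co: L/min; qh: mL/min; fub dimensionless.
    """

    donor_id: str
    bw: float
    lv: float
    lw: float
    co: float
    qh: float
    fub: float = FUB_TOLBUTAMIDE

    @classmethod
    def from_donor(cls, donor_id: str, bw: float, co: float, fub: float = FUB_TOLBUTAMIDE):
        lv, lw = liver_weight(bw)
        if co <= 0:
            raise ValueError(f"{donor_id}: cardiac output must be positive")
        return cls(donor_id=donor_id, bw=bw, lv=lv, lw=lw, co=co,
                   qh=HEPATIC_FLOW_FRACTION * co * 1000.0, fub=fub)

    def __post_init__(self):
        if not 0 < self.fub <= 1:
            raise ValueError(f"{self.donor_id}: fub must be in (0, 1]")
        if min(self.bw, self.lv, self.lw, self.co, self.qh) <= 0:
            raise ValueError(f"{self.donor_id}: physiological parameters must be positive")


def liver_weight(bw: float) -> tuple[float, float]:
    """Liver volume (mL) and weight (g) from body weight (kg)."""
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    lv = LIVER_VOLUME_SLOPE_ML_PER_KG * bw + LIVER_VOLUME_INTERCEPT_ML
    return lv, LIVER_DENSITY_G_PER_ML * lv


def clint_liver(clint_vitro: float, mppgl: float, lw: float, bw: float) -> float:
    """Whole-liver intrinsic clearance in mL/min/kg.

    µL/min/mg × mg/g × g ÷ kg = µL/min/kg; ÷1000 → mL/min/kg.
    """
    for name, v in (("clint_vitro", clint_vitro), ("mppgl", mppgl), ("lw", lw), ("bw", bw)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return clint_vitro * mppgl * lw / bw / 1000.0


def well_stirred_clh(qh_per_kg: float, fub: float, clint_liver: float) -> float:
    """Well-stirred hepatic clearance, mL/min/kg.

    CL_H = Q_H·fub·CL_int / (Q_H + fub·CL_int); strictly below both Q_H
    (flow limit) and fub·CL_int (metabolism limit).
    """
    for name, v in (("qh_per_kg", qh_per_kg), ("fub", fub), ("clint_liver", clint_liver)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    fu_cl = fub * clint_liver
    return qh_per_kg * fu_cl / (qh_per_kg + fu_cl)


def _cohort_param_frame(cohort_params: pd.DataFrame) -> pd.DataFrame:
    required = {"donor_id", "mppgl", "clint_vitro", "bw", "co"}
    missing_cols = required - set(cohort_params.columns)
    if missing_cols:
        raise ValueError(f"cohort_params missing columns: {sorted(missing_cols)}")
    bad = cohort_params[
        cohort_params[["mppgl", "clint_vitro", "bw", "co"]].le(0).any(axis=1)
        | cohort_params[["mppgl", "clint_vitro", "bw", "co"]].isna().any(axis=1)
    ]
    if len(bad):
        raise ValueError(
            f"non-positive or missing parameters for donors: {sorted(bad['donor_id'])}"
        )
    df = cohort_params.copy()
    df["lv"] = LIVER_VOLUME_SLOPE_ML_PER_KG * df["bw"] + LIVER_VOLUME_INTERCEPT_ML
    df["lw"] = LIVER_DENSITY_G_PER_ML * df["lv"]
    df["qh"] = HEPATIC_FLOW_FRACTION * df["co"] * 1000.0
    return df


def predict_cohort(
    cohort_params: pd.DataFrame,
    method: str = "all",
    fub: float = FUB_TOLBUTAMIDE,
    recompute_lw: bool = False,
) -> pd.DataFrame:
    """Per-donor hepatic clearance predictions under one or all methods.

    Parameters
    ----------
    cohort_params
        One row per donor with columns donor_id, mppgl (mg/g), clint_vitro
        (µL/min/mg), bw (kg), co (L/min).  LW and Q_H are derived.
    method
        One of "A".."G", or "all" for the full seven-method table.
    fub
        Fraction unbound in blood (single cohort-wide scalar).
    recompute_lw
        Under method F (individual BW), recompute LW from the individual BW
        instead of holding it at the cohort mean.

    Returns
    -------
    DataFrame with donor_id, method, clint_liver_ml_min_kg, clh_ml_min_kg.
    """
    methods = list(METHODS) if method == "all" else [method]
    for m in methods:
        if m not in METHOD_MASKS:
            raise ValueError(f"unknown method {m!r}; expected one of {METHODS} or 'all'")
    df = _cohort_param_frame(cohort_params)
    means = {p: float(df[p].mean()) for p in _PARAMS}

    frames = []
    for m in methods:
        mask = METHOD_MASKS[m]
        vals = {
            p: (df[p].to_numpy(dtype=float) if p in mask else np.full(len(df), means[p]))
            for p in _PARAMS
        }
        if recompute_lw and "bw" in mask and "lw" not in mask:
            lw = LIVER_DENSITY_G_PER_ML * (
                LIVER_VOLUME_SLOPE_ML_PER_KG * vals["bw"] + LIVER_VOLUME_INTERCEPT_ML
            )
        else:
            lw = vals["lw"]
        cl_liver = vals["clint_vitro"] * vals["mppgl"] * lw / vals["bw"] / 1000.0
        qh_per_kg = vals["qh"] / vals["bw"]
        fu_cl = fub * cl_liver
        clh = qh_per_kg * fu_cl / (qh_per_kg + fu_cl)
        frames.append(
            pd.DataFrame(
                {
                    "donor_id": df["donor_id"].to_numpy(),
                    "method": m,
                    "clint_liver_ml_min_kg": cl_liver,
                    "clh_ml_min_kg": clh,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
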