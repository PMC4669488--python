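"""Synthetic liver-donor cohorts with known latent scaling factors.

The study population this emulates is a bank of surgical liver samples:
each donor carries demographics (age, gender, body weight, smoking,
drinking, diagnosis), a cardiac output, a latent microsomal-protein-per-
gram-liver (MPPGL) content, and latent tolbutamide Michaelis–Menten
parameters.  Continuous traits are drawn from truncated log-normal
distributions whose underlying (µ, σ) are moment-matched to a target
arithmetic mean and SD, then restricted to stated bounds by rejection
sampling — log-normal because the measured traits are strictly positive
and right-skewed, truncated because the emulated population has printed
min/max values.  Categorical traits follow stated proportions.

Because the latent MPPGL and (Vmax, Km) are known, every downstream
estimator (the POR-ratio MPPGL estimator, the Michaelis–Menten fitter)
can be tested for exact or statistical recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .kinetics import TOLBUTAMIDE_GRID_UM, michaelis_menten

__all__ = [
    "TraitSpec",
    "IsoformActivitySpec",
    "CohortSpec",
    "Donor",
    "PORPair",
    "KineticSeries",
    "generate_cohort",
    "generate_por_pairs",
    "generate_kinetics",
    "generate_vm_table",
    "cohort_to_frame",
]

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class TraitSpec:
    """Target arithmetic mean, SD and hard bounds for one continuous trait."""

    mean: float
    sd: float
    bounds: tuple[float, float]

    def validate(self, name: str) -> None:
        lo, hi = self.bounds
        if self.sd < 0:
            raise ValueError(f"{name}: sd must be >= 0, got {self.sd}")
        if not lo < hi:
            raise ValueError(f"{name}: bounds must satisfy min < max, got {self.bounds}")
        if not (lo <= self.mean <= hi):
            raise ValueError(f"{name}: mean {self.mean} outside bounds {self.bounds}")
        if lo <= 0:
            raise ValueError(f"{name}: lower bound must be positive, got {lo}")


@dataclass(frozen=True)
class IsoformActivitySpec:
    """Median and 95% percentile interval of one CYP's per-mg activity (pmol/min/mg)."""

    median: float
    pi_lower: float
    pi_upper: float

    def validate(self, name: str) -> None:
        if not 0 < self.pi_lower < self.median < self.pi_upper:
            raise ValueError(
                f"{name}: need 0 < PI lower < median < PI upper, got "
                f"({self.pi_lower}, {self.median}, {self.pi_upper})"
            )

    def lognormal_params(self) -> tuple[float, float]:
        """(µ, σ) of the log-normal with this median and 95% PI fold-change."""
        mu = math.log(self.median)
        sigma = math.log(self.pi_upper / self.pi_lower) / (2 * 1.959963984540054)
        return mu, sigma


@dataclass
class CohortSpec:
    """Full recipe for a synthetic donor cohort.

    Continuous traits are (mean, sd, bounds) triples; per-isoform microsomal
    activities are (median, 95% PI) pairs; demographics are categorical
    proportions that must each sum to 1.
    """

    n_donors: int
    seed: int = 0
    mppgl: TraitSpec = field(default_factory=lambda: TraitSpec(39.46, 21.57, (6.71, 127.95)))
    vmax: TraitSpec = field(default_factory=lambda: TraitSpec(255.82, 79.48, (83.76, 454.80)))
    km: TraitSpec = field(default_factory=lambda: TraitSpec(235.73, 99.78, (101.20, 531.90)))
    body_weight: TraitSpec = field(default_factory=lambda: TraitSpec(60.0, 9.0, (40.0, 85.0)))
    cardiac_output: TraitSpec = field(default_factory=lambda: TraitSpec(5.0, 0.8, (3.5, 7.0)))
    vm_specs: dict[str, IsoformActivitySpec] = field(default_factory=dict)
    gender_proportions: dict[str, float] = field(
        default_factory=lambda: {"male": 40 / 128, "female": 88 / 128}
    )
    age_band_proportions: dict[str, float] = field(
        default_factory=lambda: {"20-45": 51 / 128, "46-60": 63 / 128, "61-75": 14 / 128}
    )
    smoking_rate: float = 13 / 128
    drinking_rate: float = 13 / 128
    diagnosis_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "hepatic cavernous hemangioma": 93 / 128,
            "metastatic carcinoma": 10 / 128,
            "cholelithiasis": 9 / 128,
            "gallbladder cancer": 5 / 128,
            "hepatic cholangiocarcinoma": 7 / 128,
            "hepatocellular carcinoma": 4 / 128,
        }
    )

    def validate(self) -> None:
        if self.n_donors < 0:
            raise ValueError(f"n_donors: must be >= 0, got {self.n_donors}")
        for name in ("mppgl", "vmax", "km", "body_weight", "cardiac_output"):
            getattr(self, name).validate(name)
        for iso, spec in self.vm_specs.items():
            spec.validate(f"vm_specs[{iso}]")
        for name, props in (
            ("gender_proportions", self.gender_proportions),
            ("age_band_proportions", self.age_band_proportions),
            ("diagnosis_proportions", self.diagnosis_proportions),
        ):
            if not props:
                raise ValueError(f"{name}: must be non-empty")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name}: proportions must be >= 0")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: proportions must sum to 1, got {sum(props.values())}")
        for name, rate in (("smoking_rate", self.smoking_rate), ("drinking_rate", self.drinking_rate)):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name}: must be in [0, 1], got {rate}")
        for band in self.age_band_proportions:
            lo, hi = _parse_age_band(band)
            if lo < 18:
                raise ValueError(f"age_band_proportions: band '{band}' allows ages below 18")


@dataclass
class Donor:
    """One synthetic liver donor; true_* fields are latent ground truth."""

    donor_id: str
    age: int
    gender: str
    body_weight: float  # kg
    smoking: bool
    drinking: bool
    diagnosis: str
    cardiac_output: float  # L/min
    true_mppgl: float  # mg microsomal protein / g liver
    true_vmax: float  # pmol/min/mg
    true_km: float  # µM

    def __post_init__(self):
        if self.body_weight <= 0:
            raise ValueError(f"{self.donor_id}: body_weight must be > 0")
        if self.cardiac_output <= 0:
            raise ValueError(f"{self.donor_id}: cardiac_output must be > 0")
        if self.true_mppgl <= 0:
            raise ValueError(f"{self.donor_id}: true_mppgl must be > 0")
        if self.age < 18:
            raise ValueError(f"{self.donor_id}: age must be >= 18")


@dataclass(frozen=True)
class PORPair:
    """Matched cytochrome-c reduction rates for one donor.

    homogenate_rate: nmol/min per g liver; microsome_rate: nmol/min per mg
    microsomal protein.  Their ratio is the donor's MPPGL in mg/g.
    """

    donor_id: str
    homogenate_rate: float
    microsome_rate: float

    def __post_init__(self):
        if self.homogenate_rate <= 0 or self.microsome_rate <= 0:
            raise ValueError(f"{self.donor_id}: POR rates must be positive")


@dataclass
class KineticSeries:
    """Tolbutamide concentration–rate series for one donor."""

    donor_id: str
    concentrations: np.ndarray  # µM, strictly increasing
    rates: np.ndarray  # pmol 4-OH-tolbutamide/min/mg
    noise_cv: float = 0.0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.concentrations) != len(self.rates):
            raise ValueError(f"{self.donor_id}: concentrations and rates differ in length")
        if np.any(self.concentrations <= 0) or np.any(np.diff(self.concentrations) <= 0):
            raise ValueError(f"{self.donor_id}: concentrations must be positive and strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError(f"{self.donor_id}: rates must be >= 0")


def _parse_age_band(band: str) -> tuple[int, int]:
    lo, hi = band.replace("–", "-").split("-")
    return int(lo), int(hi)


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to an arithmetic (mean, sd)."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _draw_truncated_lognormal(rng: Generator, spec: TraitSpec, n: int) -> np.ndarray:
    """Rejection-sample n values; sd == 0 degenerates to the constant mean."""
    if n == 0:
        return np.empty(0)
    if spec.sd == 0:
        return np.full(n, spec.mean)
    mu, sigma = _lognormal_mu_sigma(spec.mean, spec.sd)
    lo, hi = spec.bounds
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        draw = rng.lognormal(mu, sigma, size=max(2 * n, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
        if filled == n:
            return out
    raise RuntimeError(
        f"rejection sampling failed: bounds {spec.bounds} capture too little "
        f"mass of lognormal(mean={spec.mean}, sd={spec.sd})"
    )


_STREAMS = (
    "mppgl", "vmax", "km", "body_weight", "cardiac_output",
    "gender", "age_band", "age", "smoking", "drinking", "diagnosis",
)


def generate_cohort(spec: CohortSpec) -> list[Donor]:
    """Draw a cohort of donors; deterministic given ``spec.seed``.

    Each trait uses its own substream of the master seed, so adding a trait
    never perturbs the draws of another.
    """
    spec.validate()
    n = spec.n_donors
    children = SeedSequence(spec.seed).spawn(len(_STREAMS))
    rng = {name: default_rng(child) for name, child in zip(_STREAMS, children)}

    mppgl = _draw_truncated_lognormal(rng["mppgl"], spec.mppgl, n)
    vmax = _draw_truncated_lognormal(rng["vmax"], spec.vmax, n)
    km = _draw_truncated_lognormal(rng["km"], spec.km, n)
    bw = _draw_truncated_lognormal(rng["body_weight"], spec.body_weight, n)
    co = _draw_truncated_lognormal(rng["cardiac_output"], spec.cardiac_output, n)

    genders = rng["gender"].choice(
        list(spec.gender_proportions), p=list(spec.gender_proportions.values()), size=n
    )
    bands = rng["age_band"].choice(
        list(spec.age_band_proportions), p=list(spec.age_band_proportions.values()), size=n
    )
    age_rng = rng["age"]
    ages = np.array(
        [age_rng.integers(*(lambda b: (b[0], b[1] + 1))(_parse_age_band(b))) for b in bands],
        dtype=int,
    ) if n else np.empty(0, dtype=int)
    smoking = rng["smoking"].random(n) < spec.smoking_rate
    drinking = rng["drinking"].random(n) < spec.drinking_rate
    diagnoses = rng["diagnosis"].choice(
        list(spec.diagnosis_proportions), p=list(spec.diagnosis_proportions.values()), size=n
    )

    return [
        Donor(
            donor_id=f"D{i:04d}",
            age=int(ages[i]),
            gender=str(genders[i]),
            body_weight=float(bw[i]),
            smoking=bool(smoking[i]),
            drinking=bool(drinking[i]),
            diagnosis=str(diagnoses[i]),
            cardiac_output=float(co[i]),
            true_mppgl=float(mppgl[i]),
            true_vmax=float(vmax[i]),
            true_km=float(km[i]),
        )
        for i in range(n)
    ]


def generate_por_pairs(
    cohort: list[Donor],
    microsome_rate_mean: float = 100.0,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> list[PORPair]:
    """Matched POR rate pairs consistent with each donor's latent MPPGL.

    The microsomal rate is drawn log-normally around ``microsome_rate_mean``
    with coefficient of variation ``noise_cv``; the homogenate rate is then
    microsome_rate × true_mppgl, so the ratio estimator recovers the latent
    MPPGL exactly — assay noise scales both members of the pair.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    if microsome_rate_mean <= 0:
        raise ValueError(f"microsome_rate_mean must be > 0, got {microsome_rate_mean}")
    rng = default_rng(SeedSequence(seed))
    if noise_cv == 0:
        micro = np.full(len(cohort), microsome_rate_mean)
    else:
        mu, sigma = _lognormal_mu_sigma(microsome_rate_mean, noise_cv * microsome_rate_mean)
        micro = rng.lognormal(mu, sigma, size=len(cohort))
    return [
        PORPair(
            donor_id=d.donor_id,
            homogenate_rate=float(m * d.true_mppgl),
            microsome_rate=float(m),
        )
        for d, m in zip(cohort, micro)
    ]


def generate_kinetics(
    cohort: list[Donor],
    vmax_per_donor=None,
    km_per_donor=None,
    grid=None,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[KineticSeries]:
    """Tolbutamide series per donor: v_i = MM(C_i) · (1 + ε_i), ε_i ~ N(0, noise_cv).

    Rates are clipped at zero.  ``vmax_per_donor`` / ``km_per_donor`` default
    to each donor's latent values; pass arrays (aligned with the cohort) to
    override.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    n = len(cohort)
    vmax = np.asarray(
        [d.true_vmax for d in cohort] if vmax_per_donor is None else vmax_per_donor, dtype=float
    )
    km = np.asarray(
        [d.true_km for d in cohort] if km_per_donor is None else km_per_donor, dtype=float
    )
    if len(vmax) != n or len(km) != n:
        raise ValueError("vmax_per_donor and km_per_donor must align with the cohort")
    if np.any(vmax <= 0) or np.any(km <= 0):
        raise ValueError("Vmax and Km must be positive for every donor")
    conc = np.asarray(TOLBUTAMIDE_GRID_UM if grid is None else grid, dtype=float)
    rng = default_rng(SeedSequence(seed))
    out = []
    for i, d in enumerate(cohort):
        clean = michaelis_menten(conc, vmax[i], km[i])
        eps = rng.normal(0.0, noise_cv, size=len(conc)) if noise_cv > 0 else 0.0
        rates = np.clip(clean * (1.0 + eps), 0.0, None)
        out.append(KineticSeries(d.donor_id, conc.copy(), rates, noise_cv=noise_cv))
    return out


def generate_vm_table(
    cohort: list[Donor],
    vm_specs: dict[str, IsoformActivitySpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-donor, per-isoform microsomal activities V_M (pmol/min/mg).

    Each isoform is log-normal with log-median and log-sd reconstructed from
    its printed median and 95% percentile interval.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not vm_specs:
        raise ValueError("vm_specs must be non-empty")
    children = SeedSequence(seed).spawn(len(vm_specs))
    rows = []
    for (iso, spec), child in zip(sorted(vm_specs.items()), children):
        spec.validate(f"vm_specs[{iso}]")
        mu, sigma = spec.lognormal_params()
        vals = default_rng(child).lognormal(mu, sigma, size=len(cohort))
        for d, v in zip(cohort, vals):
            rows.append({"donor_id": d.donor_id, "isoform": iso, "vm_pmol_min_mg": float(v)})
    return pd.DataFrame(rows)


def cohort_to_frame(cohort: list[Donor]) -> pd.DataFrame:
    """Tidy per-donor table (one row per donor, documented units in names)."""
    return pd.DataFrame(
        {
            "donor_id": [d.donor_id for d in cohort],
            "age_years": [d.age for d in cohort],
            "gender": [d.gender for d in cohort],
            "bw_kg": [d.body_weight for d in cohort],
            "smoking": [d.smoking for d in cohort],
            "drinking": [d.drinking for d in cohort],
            "diagnosis": [d.diagnosis for d in cohort],
            "co_l_min": [d.cardiac_output for d in cohort],
            "true_mppgl_mg_g": [d.true_mppgl for d in cohort],
            "true_vmax_pmol_min_mg": [d.true_vmax for d in cohort],
            "true_km_uM": [d.true_km for d in cohort],
        }
    )
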