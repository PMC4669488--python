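"""Per-liver CYP activities and variability statistics.

Microsomal activities V_M (pmol/min per mg microsomal protein) are scaled
to per-gram-liver activities

    V_L [nmol/min/g] = V_M [pmol/min/mg] × MPPGL [mg/g] / 1000

Variability is summarized as the max/min fold-change and the 95% percentile
interval (2.5th–97.5th) fold-change.  Because MPPGL itself varies several
fold between donors, a donor's rank in the cohort can shift substantially
between the V_M and V_L orderings; the rank-change analysis quantifies that
shift per donor and isoform and bins it into tiny (<10% of the cohort),
moderate (10–20%), obvious (20–50%) and dramatic (>50%) bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "RankChangeReport",
    "GroupComparison",
    "CorrelationResult",
    "summarize_activity",
    "compute_vl",
    "rank_change_analysis",
    "group_compare",
    "correlate",
    "RANK_CHANGE_BANDS",
]

logger = logging.getLogger(__name__)

#: Band edges for rank-change percentages: [0,10%), [10,20%), [20,50%), [50%,100%]
RANK_CHANGE_BANDS = (
    ("tiny", 0.0, 0.10),
    ("moderate", 0.10, 0.20),
    ("obvious", 0.20, 0.50),
    ("dramatic", 0.50, 1.0 + 1e-12),
)


@dataclass(frozen=True)
class SummaryStats:
    """Location, spread and fold-change summary of a positive sample."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    p2_5: float
    p97_5: float
    fold_minmax: float
    fold_pi: float


@dataclass(frozen=True)
class RankChangeReport:
    """Per-donor rank shifts between V_M and V_L orderings.

    per_donor: one row per (donor, isoform) with both ranks, the absolute
    rank change, its fraction of cohort size and its band.
    band_shares: per isoform, the share of donors in each band (sums to 1).
    """

    per_donor: pd.DataFrame
    band_shares: pd.DataFrame
    n_donors: int


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "mann-whitney" or "kruskal-wallis"
    statistic: float
    pvalue: float
    n_groups: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    strength: str  # strong (|r|>=0.6), moderate (0.3<=|r|<0.6), weak


def summarize_activity(values, require_positive: bool = True) -> SummaryStats:
    """Mean/SD/median, extremes, 2.5/97.5 percentiles and fold-changes.

    Percentiles use linear interpolation between closest ranks.  Fold-changes
    (max/min and p97.5/p2.5) require strictly positive values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if require_positive and np.any(x <= 0):
        raise ValueError("fold-changes require strictly positive values")
    p2_5, p97_5 = np.percentile(x, [2.5, 97.5], method="linear")
    xmin, xmax = float(x.min()), float(x.max())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return SummaryStats(
        n=int(x.size),
        mean=float(x.mean()),
        sd=sd,
        median=float(np.median(x)),
        min=xmin,
        max=xmax,
        p2_5=float(p2_5),
        p97_5=float(p97_5),
        fold_minmax=xmax / xmin if require_positive else float("nan"),
        fold_pi=float(p97_5 / p2_5) if require_positive else float("nan"),
    )


def compute_vl(vm_table: pd.DataFrame, mppgl) -> pd.DataFrame:
    """Attach V_L = V_M × MPPGL / 1000 to a tidy (donor_id, isoform, vm) table.

    ``mppgl`` maps donor_id → MPPGL in mg/g (a dict, Series, or a DataFrame
    with donor_id and mppgl_mg_g columns).  Every donor in the table must
    have an estimate.
    """
    if isinstance(mppgl, pd.DataFrame):
        mapping = dict(zip(mppgl["donor_id"], mppgl["mppgl_mg_g"]))
    elif isinstance(mppgl, pd.Series):
        mapping = mppgl.to_dict()
    else:
        mapping = dict(mppgl)
    missing = sorted(set(vm_table["donor_id"]) - set(mapping))
    if missing:
        raise KeyError(f"no MPPGL estimate for donors: {missing}")
    bad = [d for d, m in mapping.items() if m <= 0]
    if bad:
        raise ValueError(f"non-positive MPPGL for donors: {sorted(bad)}")
    out = vm_table.copy()
    factors = out["donor_id"].map(mapping).astype(float)
    out["mppgl_mg_g"] = factors
    out["vl_nmol_min_g"] = out["vm_pmol_min_mg"] * factors / 1000.0
    return out


def rank_change_analysis(activity: pd.DataFrame) -> RankChangeReport:
    """Rank donors by V_M and by V_L per isoform; report absolute rank shifts.

    Ranks are ascending, 1..n, assigned in stable first-occurrence order when
    tied (ties are logged).  The rank-change percentage is the absolute rank
    difference divided by the cohort size n.
    """
    donors = activity["donor_id"].unique()
    n = len(donors)
    if n < 2:
        raise ValueError("rank-change analysis needs at least 2 donors")
    rows = []
    for iso, grp in activity.groupby("isoform", sort=True):
        if grp["donor_id"].duplicated().any():
            raise ValueError(f"isoform {iso}: duplicate donor rows")
        if len(grp) != n:
            raise ValueError(f"isoform {iso}: missing donors ({len(grp)} of {n})")
        vm = grp["vm_pmol_min_mg"].to_numpy()
        vl = grp["vl_nmol_min_g"].to_numpy()
        for name, vals in (("vm", vm), ("vl", vl)):
            if len(np.unique(vals)) != n:
                logger.warning("isoform %s: ties in %s broken by first occurrence", iso, name)
        rank_vm = stats.rankdata(vm, method="ordinal")
        rank_vl = stats.rankdata(vl, method="ordinal")
        change = np.abs(rank_vm - rank_vl)
        pct = change / n
        for did, rm, rl, ch, p in zip(grp["donor_id"], rank_vm, rank_vl, change, pct):
            rows.append(
                {
                    "donor_id": did,
                    "isoform": iso,
                    "rank_vm": int(rm),
                    "rank_vl": int(rl),
                    "abs_rank_change": int(ch),
                    "pct_change": float(p),
                    "band": _band(p),
                }
            )
    per_donor = pd.DataFrame(rows)
    shares = (
        per_donor.groupby("isoform")["band"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=[b[0] for b in RANK_CHANGE_BANDS], fill_value=0.0)
        .reset_index()
    )
    return RankChangeReport(per_donor=per_donor, band_shares=shares, n_donors=n)


def _band(pct: float) -> str:
    for name, lo, hi in RANK_CHANGE_BANDS:
        if lo <= pct < hi:
            return name
    return RANK_CHANGE_BANDS[-1][0]


def group_compare(values, groups) -> GroupComparison:
    """Nonparametric location comparison across donor subgroups.

    Two groups → two-sided Mann-Whitney U; three or more → Kruskal-Wallis H.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2:
        raise ValueError(f"need >= 2 groups, got {len(samples)}")
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs at least one observation")
    if len(samples) == 2:
        # exact null distribution when tractable and tie-free
        no_ties = len(np.unique(values)) == len(values)
        method = "exact" if (no_ties and max(map(len, samples)) <= 25) else "auto"
        stat, p = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided", method=method
        )
        return GroupComparison("mann-whitney", float(stat), float(p), 2)
    stat, p = stats.kruskal(*samples)
    return GroupComparison("kruskal-wallis", float(stat), float(p), len(samples))


def correlate(x, y) -> CorrelationResult:
    """Spearman rank correlation with the usual strength bands."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    a = abs(rho)
    strength = "strong" if a >= 0.6 else ("moderate" if a >= 0.3 else "weak")
    return CorrelationResult(float(rho), float(p), strength)
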