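"""Packaged reference inputs and the calibrated default cohort recipe.

Two kinds of fixed inputs ship with the package:

* the six literature reports of observed tolbutamide intravenous clearance
  in healthy adults, used to score predictions;
* the default :class:`~hepscale.cohort.CohortSpec`, whose marginal
  distributions are calibrated to the published population summaries of a
  128-donor Chinese liver bank (MPPGL mean 39.46 ± 21.57 mg/g, range
  6.71–127.95; tolbutamide Vmax 255.82 ± 79.48 pmol/min/mg and Km
  235.73 ± 99.78 µM; per-isoform microsomal activity medians and 95%
  percentile intervals for ten CYPs; demographic category proportions).
"""

from __future__ import annotations

from .accuracy import ObservedClearance, ObservedClearanceSet
from .cohort import CohortSpec, IsoformActivitySpec
from .kinetics import TOLBUTAMIDE_GRID_UM

__all__ = [
    "TOLBUTAMIDE_GRID_UM",
    "CYP_VM_SPECS",
    "observed_tolbutamide_clearance",
    "default_cohort_spec",
]

#: Published median and 95% percentile interval of microsomal activity
#: (pmol/min/mg) per CYP isoform, each measured with its selective probe
#: reaction in 78 livers.
CYP_VM_SPECS: dict[str, IsoformActivitySpec] = {
    "CYP1A2": IsoformActivitySpec(677.94, 169.20, 1344.69),
    "CYP2A6": IsoformActivitySpec(267.92, 12.19, 689.73),
    "CYP2B6": IsoformActivitySpec(46.67, 12.16, 151.14),
    "CYP2C8": IsoformActivitySpec(31.50, 4.34, 74.27),
    "CYP2C9": IsoformActivitySpec(222.70, 76.17, 391.49),
    "CYP2C19": IsoformActivitySpec(97.62, 9.98, 274.83),
    "CYP2D6": IsoformActivitySpec(68.16, 9.06, 190.03),
    "CYP2E1": IsoformActivitySpec(486.92, 198.24, 1061.97),
    "CYP3A4/5": IsoformActivitySpec(836.56, 178.15, 2967.83),
}


def observed_tolbutamide_clearance() -> ObservedClearanceSet:
    """Six literature reports of tolbutamide intravenous CL_H (mL/min/kg).

    Three arms from Back et al., plus Miners et al., Wilner et al. and
    Wing et al.; two reports carry no SD.
    """
    return ObservedClearanceSet(
        entries=(
            ObservedClearance("back_a", 0.260, sd=0.100, n_subjects=7),
            ObservedClearance("back_b", 0.226, sd=0.024, n_subjects=6),
            ObservedClearance("back_c", 0.239, sd=0.050, n_subjects=6),
            ObservedClearance("miners", 0.171, sd=None, n_subjects=6),
            ObservedClearance("wilner", 0.147, sd=0.013, n_subjects=6),
            ObservedClearance("wing", 0.159, sd=None, n_subjects=7),
        )
    )


def default_cohort_spec(n_donors: int = 128, seed: int = 0) -> CohortSpec:
    """The calibrated cohort recipe (see module docstring for provenance)."""
    return CohortSpec(n_donors=n_donors, seed=seed, vm_specs=dict(CYP_VM_SPECS))
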