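"""Physiological model of ATP-competitive TORC1 inhibition by IAA.

The potency of an ATP-competitive inhibitor in the cell depends on the
prevailing ATP concentration through the Cheng-Prusoff relation

    IC50_eff = Ki * (1 + [ATP] / Km_ATP)

and the fractional inhibition at inhibitor concentration [I] is

    % inhibition = 100 * [I] / ([I] + IC50_eff).

The module also converts LC-MS isotope-dilution measurements (analyte /
internal-standard peak-area ratios against a calibration line) into absolute
amounts, amounts into intracellular concentrations given cell number and
volume, and keeps the generation/copy-number bookkeeping used for expanded
clone libraries (g = log2(N_end / N_start), copies per founder = 2^g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError
from .units import micromolar_from_pmol, round_sig


@dataclass(frozen=True)
class PhysiologicalState:
    """Intracellular ATP and IAA concentrations for one growth condition."""

    atp: float  # μM
    iaa: float  # μM
    label: str = ""

    def __post_init__(self) -> None:
        if self.atp < 0 or self.iaa < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class InhibitionPrediction:
    ic50_effective: float  # μM
    pct_inhibition: float  # %
    ic50_unrounded: float = float("nan")
    paper_rounding: bool = False
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "ic50_effective_uM": self.ic50_effective,
            "pct_inhibition": self.pct_inhibition,
            "ic50_unrounded_uM": self.ic50_unrounded,
            "paper_rounding": self.paper_rounding,
            "label": self.label,
        }


def effective_ic50(ki: float, atp: float, km_atp: float) -> float:
    """Cheng-Prusoff effective IC50 (μM) of an ATP-competitive inhibitor."""
    if ki <= 0 or km_atp <= 0:
        raise ValueError("Ki and Km_ATP must be positive")
    if atp < 0:
        raise ValueError("[ATP] must be non-negative")
    return ki * (1.0 + atp / km_atp)


def percent_inhibition(inhibitor: float, ic50: float) -> float:
    """Fractional target inhibition (%) at a given inhibitor concentration."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if inhibitor < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    return 100.0 * inhibitor / (inhibitor + ic50)


def predict_state(
    ki: float, km_atp: float, state: PhysiologicalState, paper_rounding: bool = False
) -> InhibitionPrediction:
    """Chain effective_ic50 and percent_inhibition for one physiological state.

    With ``paper_rounding`` the effective IC50 is rounded to 2 significant
    figures before the inhibition step, matching how the headline numbers are
    usually quoted; the unrounded value is kept alongside.
    """
    ic50 = effective_ic50(ki, state.atp, km_atp)
    ic50_used = round_sig(ic50, 2) if paper_rounding else ic50
    pct = percent_inhibition(state.iaa, ic50_used)
    return InhibitionPrediction(ic50_used, pct, ic50_unrounded=ic50,
                                paper_rounding=paper_rounding, label=state.label)


# ---------------------------------------------------------------------------
# concentrations from amounts


@dataclass(frozen=True)
class CellSample:
    """A harvested cell sample with a measured analyte amount."""

    n_cells: float
    cell_volume: float  # fL per cell
    analyte_amount: float  # pmol

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.analyte_amount < 0:
            raise ValueError("cell number and amount must be non-negative")
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")


def intracellular_concentration(sample: CellSample) -> float:
    """Intracellular concentration (μM) = amount / total cell volume."""
    if sample.n_cells <= 0:
        raise ValueError("need a positive cell count")
    return micromolar_from_pmol(sample.analyte_amount, sample.n_cells * sample.cell_volume)


# ---------------------------------------------------------------------------
# isotope-dilution quantification


@dataclass
class CalibrationCurve:
    """Analyte/IS amount-ratio vs area-ratio calibration, fit by unweighted OLS."""

    points: list[tuple[float, float]]  # (amount_ratio, area_ratio)
    slope: float = field(init=False, default=float("nan"))
    intercept: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise CalibrationError("need at least 2 calibration points")
        x = np.array([p[0] for p in self.points], dtype=float)
        y = np.array([p[1] for p in self.points], dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0:
            raise CalibrationError(f"calibration slope must be positive, got {slope:.4g}")
        self.slope = float(slope)
        self.intercept = float(intercept)


@dataclass(frozen=True)
class LCMSMeasurement:
    """One sample's analyte and internal-standard peak areas."""

    analyte_area: float
    is_area: float
    is_amount: float  # pmol of spiked internal standard

    def __post_init__(self) -> None:
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be positive")
        if self.analyte_area < 0:
            raise ValueError("analyte area must be non-negative")
        if self.is_amount <= 0:
            raise ValueError("internal-standard amount must be positive")

    @property
    def area_ratio(self) -> float:
        return self.analyte_area / self.is_area


@dataclass(frozen=True)
class QuantResult:
    amount_pmol: float
    clipped: bool = False  # True when a negative back-calculation was clipped to 0


def quantify_isotope_dilution(m: LCMSMeasurement, cal: CalibrationCurve) -> QuantResult:
    """Back-calculate the absolute analyte amount from the calibration line.

    amount = ((area_ratio - intercept) / slope) * is_amount; negative
    back-calculations (below-blank noise) are clipped to 0 and flagged.
    """
    amount = (m.area_ratio - cal.intercept) / cal.slope * m.is_amount
    if amount < 0:
        return QuantResult(0.0, clipped=True)
    return QuantResult(float(amount))


# ---------------------------------------------------------------------------
# growth bookkeeping


@dataclass(frozen=True)
class GrowthRecord:
    n_start: float
    n_end: float
    generations: float
    copies_per_founder: float


def copies_from_generations(g: float) -> float:
    """Copies per founder clone after g generations of doubling: 2^g."""
    if g < 0:
        raise ValueError("generations must be non-negative")
    return 2.0**g


def growth_bookkeeping(n_start: float, n_end: float) -> GrowthRecord:
    """Generations and copy number from start/end cell counts."""
    if n_start <= 0 or n_end <= 0:
        raise ValueError("cell counts must be positive")
    g = math.log2(n_end / n_start)
    return GrowthRecord(n_start, n_end, g, copies_from_generations(max(g, 0.0)) if g >= 0
                        else 2.0**g)
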