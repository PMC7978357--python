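"""Unit conversions used by the physiology calculations.

All concentrations inside the package are micromolar (μM); amounts are
picomoles (pmol) and cell volumes femtoliters (fL).  Centralizing the
conversions keeps the dimensional analysis in one tested place:

    1 pmol = 1e-12 mol,  1 fL = 1e-15 L
    => 1 pmol / 1 fL = 1e3 mol/L = 1e9 μM
    => 1 pmol per 1e6 fL = 1 mM = 1e3 μM
"""

from __future__ import annotations

import math

#: micromolar concentration of 1 pmol dissolved in 1 fL
UM_PER_PMOL_PER_FL = 1e9


def micromolar_from_pmol(amount_pmol: float, volume_fl: float) -> float:
    """Concentration in μM of ``amount_pmol`` in a volume of ``volume_fl``."""
    if volume_fl <= 0:
        raise ValueError(f"volume must be positive, got {volume_fl} fL")
    if amount_pmol < 0:
        raise ValueError(f"amount must be non-negative, got {amount_pmol} pmol")
    return amount_pmol / volume_fl * UM_PER_PMOL_PER_FL


def micromolar_from_pmol_per_ml(amount_pmol: float, volume_ml: float) -> float:
    """Concentration in μM of ``amount_pmol`` in ``volume_ml`` of medium."""
    return micromolar_from_pmol(amount_pmol, volume_ml * 1e12)  # 1 mL = 1e12 fL


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
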