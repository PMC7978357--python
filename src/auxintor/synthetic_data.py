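"""Seeded generators for every input the pipeline consumes.

Each generator returns its output table(s) together with a
:class:`SimulationTruth` record carrying the seed and the ground truth, so
downstream stages can be tested as recovery problems without external data.

Models
------
* Transposon libraries: each clone carries one insertion; after ``g``
  generations a clone with relative fitness ``f`` has expanded to ``2**(g*f)``
  copies.  Fitness effects encode drug sensitivity, so they act during the
  treated expansion; the control culture expands neutrally.  Sequencing reads
  are drawn multinomially with clone abundances as weights, so library read
  totals are conserved exactly.
* Colony screens: a sensitive subpopulation grows to ``(1 - effect)`` of the
  control expectation on drug plates; per-plate scale factors emulate batch
  effects that plate-median normalization must remove.
* Continuous assays (velocities, colony sizes, LC-MS areas): multiplicative
  Gaussian noise ``x * (1 + eps)``, ``eps ~ N(0, cv)``, truncated at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemgen_screen import ColonyTable
from .errors import SimulationSpecError
from .genome import GenomeSpec
from .inhibition_kinetics import KineticParams, four_pl, velocity
from .satay_fitness import InsertionTable


@dataclass
class SimulationTruth:
    """Ground truth emitted by every generator, keyed by the seed that made it."""

    seed: int
    per_gene_fitness: dict[str, float] | None = None
    generations_control: float | None = None
    generations_treated: float | None = None
    sensitive_strains: set[str] = field(default_factory=set)
    kinetic_params: KineticParams | None = None
    dose_response_params: tuple[float, float, float, float] | None = None
    true_amounts: list[float] | None = None
    lcms_slope: float | None = None
    lcms_intercept: float | None = None

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["sensitive_strains"] = sorted(self.sensitive_strains)
        if self.kinetic_params is not None:
            d["kinetic_params"] = self.kinetic_params.to_dict()
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# transposon library pair


def simulate_satay_pair(
    genome: GenomeSpec,
    per_gene_fitness: Mapping[str, float],
    n_clones: int,
    library_reads: int,
    g_control: float,
    g_treated: float,
    intergenic_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[InsertionTable, InsertionTable, SimulationTruth]:
    """Simulate matched control/treated insertion libraries.

    Every clone gets one insertion: with probability ``intergenic_fraction``
    at a uniform intergenic position, otherwise in a uniformly chosen gene at
    a uniform position within its body.  Reads for each condition are a
    single multinomial draw of ``library_reads`` over clones weighted by
    ``2**(g * f)`` (f = 1 for every clone in the control culture and for
    intergenic clones).  Clones sharing a position are aggregated.
    """
    if n_clones < 1 or library_reads < 1:
        raise SimulationSpecError("n_clones and library_reads must be >= 1")
    if not (0 <= intergenic_fraction < 1):
        raise SimulationSpecError("intergenic_fraction must be in [0, 1)")
    if g_control < 0 or g_treated < 0:
        raise SimulationSpecError("generation counts must be non-negative")
    if not genome.genes and intergenic_fraction == 0:
        raise SimulationSpecError("empty gene set requires intergenic_fraction > 0")
    fitness = {g.gene_id: float(per_gene_fitness.get(g.gene_id, 1.0)) for g in genome.genes}
    if any(f < 0 for f in fitness.values()):
        raise SimulationSpecError("fitness values must be >= 0")
    unknown = set(per_gene_fitness) - set(fitness)
    if unknown:
        raise SimulationSpecError(f"fitness given for unknown genes: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    genes = genome.genes
    inter = genome.intergenic_intervals()
    inter_lengths = np.array([e - s + 1 for _, s, e in inter], dtype=float)
    if intergenic_fraction > 0 and inter_lengths.sum() == 0:
        raise SimulationSpecError("no intergenic space available")

    is_inter = rng.random(n_clones) < intergenic_fraction if genes else np.ones(n_clones, bool)
    chroms = np.empty(n_clones, dtype=object)
    positions = np.empty(n_clones, dtype=int)
    clone_fitness = np.ones(n_clones, dtype=float)

    genic_idx = np.flatnonzero(~is_inter)
    if genic_idx.size:
        gene_choice = rng.integers(0, len(genes), size=genic_idx.size)
        for i, gi in zip(genic_idx, gene_choice):
            g = genes[gi]
            chroms[i] = g.chrom
            positions[i] = rng.integers(g.start, g.end + 1)
            clone_fitness[i] = fitness[g.gene_id]
    inter_idx = np.flatnonzero(is_inter)
    if inter_idx.size:
        p = inter_lengths / inter_lengths.sum()
        iv_choice = rng.choice(len(inter), size=inter_idx.size, p=p)
        for i, ii in zip(inter_idx, iv_choice):
            chrom, s, e = inter[ii]
            chroms[i] = chrom
            positions[i] = rng.integers(s, e + 1)
    strands = rng.choice(["+", "-"], size=n_clones)

    def _draw(gens: float, f: np.ndarray) -> np.ndarray:
        logw = gens * f * np.log(2.0)
        w = np.exp(logw - logw.max())
        return rng.multinomial(library_reads, w / w.sum())

    reads_control = _draw(g_control, np.ones(n_clones))
    reads_treated = _draw(g_treated, clone_fitness)

    def _table(reads: np.ndarray, label: str) -> InsertionTable:
        df = pd.DataFrame(
            {"chrom": chroms, "pos": positions, "strand": strands, "reads": reads}
        )
        df = df[df["reads"] > 0]
        df = (
            df.groupby(["chrom", "pos", "strand"], as_index=False)["reads"]
            .sum()
            .sort_values(["chrom", "pos", "strand"])
            .reset_index(drop=True)
        )
        return InsertionTable(df, label)

    truth = SimulationTruth(
        seed=seed,
        per_gene_fitness=fitness,
        generations_control=g_control,
        generations_treated=g_treated,
    )
    return _table(reads_control, "control"), _table(reads_treated, "treated"), truth


# ---------------------------------------------------------------------------
# colony-size screen


def simulate_colony_screen(
    n_mutants: int,
    sensitive_fraction: float,
    effect: float = 0.5,
    noise_sd: float = 0.05,
    plates: int = 1,
    replicates: int = 4,
    seed: int = 0,
    base_size: float = 100.0,
    plate_effect_sd: float = 0.1,
) -> tuple[ColonyTable, ColonyTable, SimulationTruth]:
    """Simulate a deletion-collection spot screen with a sensitive subpopulation.

    Sensitive strains (drawn without replacement) have drug-plate expectation
    ``(1 - effect)`` times the control expectation.  Per-plate lognormal scale
    factors (sd ``plate_effect_sd``) emulate plate-to-plate pinning variation.
    """
    if replicates < 1:
        raise SimulationSpecError("replicates must be >= 1")
    if not (0 <= sensitive_fraction <= 1):
        raise SimulationSpecError("sensitive_fraction must be in [0, 1]")
    if not effect > 0:
        raise SimulationSpecError("effect must be > 0")
    if n_mutants < 1 or plates < 1 or noise_sd < 0:
        raise SimulationSpecError("invalid n_mutants/plates/noise_sd")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_mutants)))
    strains = np.array([f"S{i + 1:0{width}d}" for i in range(n_mutants)])
    n_sensitive = int(round(sensitive_fraction * n_mutants))
    sensitive = set(rng.choice(strains, size=n_sensitive, replace=False)) if n_sensitive else set()
    plate_ids = np.array([f"P{(i % plates) + 1}" for i in range(n_mutants)])

    def _condition(label: str, drug: bool) -> ColonyTable:
        scale = {f"P{p + 1}": float(np.exp(rng.normal(0, plate_effect_sd))) for p in range(plates)}
        rows = []
        for strain, plate in zip(strains, plate_ids):
            mean = base_size * scale[plate]
            if drug and strain in sensitive:
                mean *= 1.0 - effect
            sizes = np.maximum(mean * (1.0 + rng.normal(0, noise_sd, size=replicates)), 0.0)
            for rep, size in enumerate(sizes, start=1):
                rows.append((strain, plate, rep, float(size)))
        df = pd.DataFrame(rows, columns=["strain", "plate", "replicate", "size"])
        return ColonyTable(df, label)

    truth = SimulationTruth(seed=seed, sensitive_strains=sensitive)
    return _condition("control", False), _condition("drug", True), truth


# ---------------------------------------------------------------------------
# enzyme kinetics


def simulate_kinetics(
    params: KineticParams,
    substrate_grid: Sequence[float],
    inhibitor_levels: Sequence[float] = (0.0, 20.0, 40.0),
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Velocity observations on a substrate x inhibitor grid with CV noise."""
    if cv < 0:
        raise SimulationSpecError("cv must be >= 0")
    if replicates < 1:
        raise SimulationSpecError("replicates must be >= 1")
    substrate_grid = list(substrate_grid)
    inhibitor_levels = list(inhibitor_levels)
    if not substrate_grid or not inhibitor_levels:
        raise SimulationSpecError("substrate and inhibitor grids must be non-empty")
    if any(s <= 0 for s in substrate_grid):
        raise SimulationSpecError("substrate concentrations must be positive")
    if any(i < 0 for i in inhibitor_levels):
        raise SimulationSpecError("inhibitor concentrations must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    for inhibitor in inhibitor_levels:
        for substrate in substrate_grid:
            v0 = velocity(params, substrate, inhibitor)
            for rep in range(1, replicates + 1):
                v = max(v0 * (1.0 + rng.normal(0, cv)), 0.0) if cv > 0 else v0
                rows.append((substrate, inhibitor, v, rep))
    data = pd.DataFrame(rows, columns=["substrate_uM", "inhibitor_uM", "velocity", "replicate"])
    return data, SimulationTruth(seed=seed, kinetic_params=params)


# ---------------------------------------------------------------------------
# dose-response


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Sequence[float] = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0),
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Noisy 4PL inhibition curve; the noiseless response at dose = IC50 is
    exactly the top/bottom midpoint."""
    if hill == 0:
        raise SimulationSpecError("hill slope must be non-zero")
    if ic50 <= 0:
        raise SimulationSpecError("ic50 must be positive")
    doses = list(doses)
    if any(d < 0 for d in doses):
        raise SimulationSpecError("doses must be non-negative")
    if cv < 0 or replicates < 1:
        raise SimulationSpecError("invalid cv/replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        r0 = four_pl(d, ic50, hill, top, bottom)
        for rep in range(1, replicates + 1):
            r = max(r0 * (1.0 + rng.normal(0, cv)), 0.0) if cv > 0 else r0
            rows.append((d, r, rep))
    data = pd.DataFrame(rows, columns=["dose", "response", "replicate"])
    return data, SimulationTruth(seed=seed, dose_response_params=(ic50, hill, top, bottom))


# ---------------------------------------------------------------------------
# isotope-dilution LC-MS

#: default analyte/IS amount-ratio levels of the 6-point calibration series
CALIBRATION_RATIOS = (0.1, 0.25, 0.5, 1.0, 2.5, 5.0)


def simulate_lcms(
    true_amounts: Sequence[float],
    is_amount: float = 10.0,
    slope: float = 1.0,
    intercept: float = 0.0,
    cv: float = 0.05,
    seed: int = 0,
    calibration_ratios: Sequence[float] = CALIBRATION_RATIOS,
    is_area: float = 1e6,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Isotope-dilution measurements plus a parallel calibration series.

    The response model is area_ratio = (slope * amount/IS + intercept) * (1+eps).
    Returns (measurements, calibration, truth); the calibration table has one
    noisy point per ratio level (6 by default).
    """
    if is_amount <= 0:
        raise SimulationSpecError("internal-standard amount must be positive")
    if slope <= 0:
        raise SimulationSpecError("response slope must be positive")
    if cv < 0:
        raise SimulationSpecError("cv must be >= 0")
    if any(a < 0 for a in true_amounts):
        raise SimulationSpecError("amounts must be non-negative")
    rng = np.random.default_rng(seed)

    meas_rows = []
    for i, amount in enumerate(true_amounts, start=1):
        ratio0 = slope * amount / is_amount + intercept
        noise = (1.0 + rng.normal(0, cv)) if cv > 0 else 1.0
        ratio = max(ratio0 * noise, 0.0)
        meas_rows.append((f"sample{i}", ratio * is_area, is_area, is_amount))
    measurements = pd.DataFrame(
        meas_rows, columns=["sample", "analyte_area", "is_area", "is_amount"]
    )

    cal_rows = []
    for r in calibration_ratios:
        ratio0 = slope * r + intercept
        noise = (1.0 + rng.normal(0, cv)) if cv > 0 else 1.0
        cal_rows.append((r, max(ratio0 * noise, 0.0)))
    calibration = pd.DataFrame(cal_rows, columns=["amount_ratio", "area_ratio"])

    truth = SimulationTruth(
        seed=seed, true_amounts=[float(a) for a in true_amounts],
        lcms_slope=slope, lcms_intercept=intercept,
    )
    return measurements, calibration, truth
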