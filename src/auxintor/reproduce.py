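"""End-to-end reproduction of the pipeline's headline quantitative results.

``run_paper_reproduction`` executes, from scratch, the analytic physiology
numbers (effective IC50s, percent inhibition, overlap percentage, copies per
founder) and the seeded simulation-recovery suite (competitive-fit Km/Ki,
dose-response IC50s, transposon-screen depleted-gene recovery), and reports
each check with its computed value, expected value, and pass/fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import chemgen_screen, inhibition_kinetics, physiology_model, satay_fitness
from . import synthetic_data
from .genome import tiled_genome
from .inhibition_kinetics import KineticParams
from .physiology_model import PhysiologicalState
from .units import round_sig

#: configuration keys understood by run_paper_reproduction, with defaults
DEFAULT_CONFIG: dict[str, Any] = {
    "ki": 2.4,  # μM, inhibition constant of IAA for TORC1
    "km_atp": 50.5,  # μM, Michaelis constant of TORC1 for ATP
    "atp_exponential": 3000.0,  # μM
    "atp_stationary": 56.0,  # μM
    "iaa_stationary": 10.0,  # μM
    "vmax": 100.0,  # arbitrary signal units for simulated velocities
    "kinetics_cv": 0.05,
    "kinetics_replicates": 3,
    "substrate_min": 10.0,  # μM ATP
    "substrate_max": 1000.0,
    "substrate_points": 8,
    "inhibitor_levels": [0.0, 20.0, 40.0],  # μM IAA
    "growth_ic50": 0.6,  # mM, growth inhibition
    "torc1_ic50": 2.35,  # mM, in vivo TORC1 readout (pThr737)
    "dose_cv": 0.05,
    "dose_replicates": 3,
    "overlap_n_a": 156,  # IAA-sensitive deletion strains
    "overlap_n_b": 276,  # rapamycin-sensitive deletion strains
    "overlap_n_intersect": 85,
    "generations_library": 12.7,  # expansion of the transposon library
    "satay_n_genes": 1000,
    "satay_n_depleted": 50,
    "satay_fitness": 0.5,
    "satay_g_control": 5.46,
    "satay_g_treated": 4.17,
    "satay_n_clones": 100_000,
    "satay_library_reads": 5_000_000,
    "recovery_tolerance": 0.15,  # relative, for Km/Ki/IC50 recovery
}


def build_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge overrides into the default configuration, rejecting unknown keys."""
    config = dict(DEFAULT_CONFIG)
    if overrides:
        unknown = sorted(set(overrides) - set(DEFAULT_CONFIG))
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        config.update({k: v for k, v in overrides.items() if v is not None})
    return config


@dataclass
class Check:
    name: str
    computed: float
    expected: float
    criterion: str
    passed: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ReproductionReport:
    seed: int
    checks: list[Check] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "all_passed": self.all_passed,
            "checks": [c.to_dict() for c in self.checks],
        }

    def to_text(self) -> str:
        lines = [f"paper-reproduction report (seed={self.seed})", ""]
        for c in self.checks:
            mark = "PASS" if c.passed else "FAIL"
            lines.append(
                f"[{mark}] {c.name}: computed {c.computed:.6g}, "
                f"expected {c.expected:.6g} ({c.criterion})"
            )
        lines.append("")
        lines.append("ALL CHECKS PASSED" if self.all_passed else "SOME CHECKS FAILED")
        return "\n".join(lines)


def _rel_check(name: str, computed: float, expected: float, tol: float) -> Check:
    ok = np.isfinite(computed) and abs(computed - expected) <= tol * abs(expected)
    return Check(name, float(computed), float(expected), f"within {tol:.0%}", bool(ok))


def run_paper_reproduction(
    config: dict[str, Any] | None = None, seed: int = 0
) -> ReproductionReport:
    cfg = build_config(config)
    report = ReproductionReport(seed=seed)
    add = report.checks.append

    # --- analytic physiology numbers -------------------------------------
    ic50_exp = physiology_model.effective_ic50(cfg["ki"], cfg["atp_exponential"], cfg["km_atp"])
    add(Check("effective_ic50_exponential_uM", ic50_exp, 145.0,
              "matches 145 at printed precision (|Δ| <= 0.5)", abs(ic50_exp - 145.0) <= 0.5))

    ic50_stat = physiology_model.effective_ic50(cfg["ki"], cfg["atp_stationary"], cfg["km_atp"])
    add(Check("effective_ic50_stationary_uM", ic50_stat, 5.1,
              "matches 5.1 at 2 significant figures", round_sig(ic50_stat, 2) == 5.1))

    pred = physiology_model.predict_state(
        cfg["ki"], cfg["km_atp"],
        PhysiologicalState(cfg["atp_stationary"], cfg["iaa_stationary"], "stationary day 3"),
        paper_rounding=True,
    )
    add(Check("pct_inhibition_stationary", pred.pct_inhibition, 66.2,
              "matches 66.2% at one decimal", round(pred.pct_inhibition, 1) == 66.2))

    shared = {f"mut{i:04d}" for i in range(cfg["overlap_n_intersect"])}
    only_a = {f"a{i:04d}" for i in range(cfg["overlap_n_a"] - cfg["overlap_n_intersect"])}
    only_b = {f"b{i:04d}" for i in range(cfg["overlap_n_b"] - cfg["overlap_n_intersect"])}
    venn = chemgen_screen.overlap_stats(shared | only_a, shared | only_b)
    add(Check("pct_iaa_sensitive_also_rap_sensitive", venn.pct_a_in_b, 54.0,
              ">= 54%", venn.pct_a_in_b >= 54.0))

    copies = physiology_model.copies_from_generations(cfg["generations_library"])
    add(Check("copies_per_founder", copies, 7e3,
              "7e3 at one significant figure", round_sig(copies, 1) == 7e3))

    # --- seeded recovery suite --------------------------------------------
    tol = cfg["recovery_tolerance"]
    truth_params = KineticParams("competitive", cfg["vmax"], cfg["km_atp"], cfg["ki"])
    grid = np.geomspace(cfg["substrate_min"], cfg["substrate_max"], cfg["substrate_points"])
    kin_data, _ = synthetic_data.simulate_kinetics(
        truth_params, grid, cfg["inhibitor_levels"], cv=cfg["kinetics_cv"],
        replicates=cfg["kinetics_replicates"], seed=seed,
    )
    fit = inhibition_kinetics.fit_model(kin_data, "competitive")
    add(_rel_check("km_atp_recovered_uM", fit.params.km, cfg["km_atp"], tol))
    add(_rel_check("ki_iaa_recovered_uM", fit.params.ki, cfg["ki"], tol))

    for name, ic50_mM, sub_seed in (
        ("growth_ic50_recovered_mM", cfg["growth_ic50"], seed + 1),
        ("torc1_ic50_recovered_mM", cfg["torc1_ic50"], seed + 2),
    ):
        doses = [0.0] + list(np.geomspace(ic50_mM / 12, ic50_mM * 8, 8))
        dr_data, _ = synthetic_data.simulate_dose_response(
            ic50_mM, hill=1.0, top=100.0, bottom=0.0, doses=doses,
            cv=cfg["dose_cv"], replicates=cfg["dose_replicates"], seed=sub_seed,
        )
        dr_fit = inhibition_kinetics.fit_ic50(dr_data["dose"], dr_data["response"])
        add(_rel_check(name, dr_fit.ic50, ic50_mM, tol))

    # transposon screen: depleted genes must land in the bottom score decile
    genome = tiled_genome(cfg["satay_n_genes"])
    depleted = genome.gene_ids[: cfg["satay_n_depleted"]]
    fitness_map = {g: cfg["satay_fitness"] for g in depleted}
    control, treated, _ = synthetic_data.simulate_satay_pair(
        genome, fitness_map, n_clones=cfg["satay_n_clones"],
        library_reads=cfg["satay_library_reads"],
        g_control=cfg["satay_g_control"], g_treated=cfg["satay_g_treated"],
        intergenic_fraction=0.1, seed=seed,
    )
    counts_c = satay_fitness.assign_insertions(control, genome)
    counts_t = satay_fitness.assign_insertions(treated, genome)
    scores = satay_fitness.score_genes(counts_t, counts_c, mode="reads")
    scores = satay_fitness.classify_percentiles(scores)
    bottom = set(scores.loc[scores["band"] == satay_fitness.DEPLETED, "gene_id"])
    frac = len(bottom & set(depleted)) / len(depleted)
    add(Check("satay_depleted_gene_recovery", frac, 0.9, ">= 90% in bottom decile",
              frac >= 0.9))

    return report
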