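# auxintor

Quantitative analyses of how the auxin indole-3-acetic acid (IAA) limits
growth in budding yeast by acting as an ATP-competitive inhibitor of TORC1,
the conserved growth-controlling kinase complex.

The package is for computational biologists who want to run, test, or reuse
the individual analysis stages of that story on their own (or synthetic)
data:

- **`synthetic_data`** — seeded generators with ground-truth records for
  every input the pipeline consumes: transposon insertion libraries expanded
  over known generation counts with per-gene fitness effects and multinomial
  read sampling; deletion-collection colony screens with a sensitive
  subpopulation; enzyme velocities under a chosen inhibition mechanism;
  logistic dose-response curves; isotope-dilution LC-MS calibration series.
- **`satay_fitness`** — per-gene fitness from transposon insertion tables:
  normalized log2 treated/control scores, 10th/90th-percentile bands, and
  cross-treatment concordance.
- **`chemgen_screen`** — colony-size chemical-genetic screening: plate-median
  normalization, robust (median/MAD) z-scores with sensitivity calls at
  z ≥ 1.88, Venn overlaps with exact hypergeometric enrichment.
- **`inhibition_kinetics`** — global fits of steady-state rate laws
  (competitive / noncompetitive / uncompetitive / mixed), mechanism
  discrimination by AICc, bootstrap confidence intervals, and 4-parameter
  logistic IC50 fitting.
- **`physiology_model`** — the Cheng-Prusoff model of inhibition at cellular
  ATP, `IC50 = Ki·(1 + [ATP]/Km_ATP)` and `% inhibition = [I]/([I] + IC50)`,
  plus isotope-dilution quantification, intracellular-concentration
  conversion, and generation/copy-number bookkeeping.

A `click` CLI (`auxintor`) wires all stages, including an end-to-end
`reproduce-paper` command that recomputes the headline numbers and the seeded
recovery suite and exits non-zero if any check fails.

## Worked example

Why does a micromolar-affinity ATP-competitor only bite in stationary phase?
Because its effective IC50 scales with cellular ATP:

```python
from auxintor import physiology_model as pm

for label, atp, iaa in [("exponential", 3000.0, 0.2), ("stationary day 3", 56.0, 10.0)]:
    pred = pm.predict_state(2.4, 50.5, pm.PhysiologicalState(atp, iaa, label),
                            paper_rounding=True)
    print(f"{label:18s} effective IC50 = {pred.ic50_effective:7.2f} uM   "
          f"inhibition at {iaa:5.1f} uM IAA = {pred.pct_inhibition:5.2f} %")
```

```
exponential        effective IC50 =  140.00 uM   inhibition at   0.2 uM IAA =  0.14 %
stationary day 3   effective IC50 =    5.10 uM   inhibition at  10.0 uM IAA = 66.23 %
```

With Ki = 2.4 μM and Km_ATP = 50.5 μM, exponential-phase ATP (3 mM) pushes
the effective IC50 to ~145 μM, so the trace amounts of IAA present (<0.2 μM)
are irrelevant; when ATP collapses to 56 μM in stationary phase the IC50
drops to 5.1 μM and the ~10 μM of IAA that accumulates is predicted to
inhibit TORC1 by 66% — a metabolic brake on growth during quiescence entry.

The kinetic parameters themselves come out of mechanism-discriminating fits.
On synthetic velocities generated under the competitive rate law (Km 50.5 μM,
Ki 2.4 μM, 5% noise):

```python
import numpy as np
from auxintor import synthetic_data as sd, inhibition_kinetics as ik
from auxintor.inhibition_kinetics import KineticParams

truth = KineticParams("competitive", 100.0, 50.5, 2.4)
data, _ = sd.simulate_kinetics(truth, np.geomspace(10, 1000, 8), [0, 20, 40],
                               cv=0.05, replicates=3, seed=1)
for f in ik.select_mechanism(data, ("MM", "competitive", "noncompetitive",
                                    "uncompetitive")):
    print(f"{f.params.mechanism:15s} AICc = {f.aicc:8.1f}   Km = {f.params.km:6.1f}   "
          f"Ki = {f.params.ki if f.params.ki else float('nan'):6.2f}")
```

```
competitive     AICc =     59.6   Km =   51.5   Ki =   2.37
noncompetitive  AICc =    316.3   Km =   95.0   Ki =  20.01
uncompetitive   AICc =    362.1   Km =  106.2   Ki =  15.35
MM              AICc =    438.4   Km =  159.9   Ki =    nan
```

The competitive model wins decisively and recovers both constants within a
few percent. The same checks, plus the transposon-screen and dose-response
recoveries, run from the shell:

```bash
auxintor reproduce-paper --seed 0 --out results/
```

See `docs/methods.md` for the models, noise assumptions, numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

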