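# greenextract

Toolkit for assessing the substitution of an extraction solvent (reference:
n-hexane, alternative: 2-methyltetrahydrofuran) in vegetable-oil crushing,
covering the full decision chain:

* **`greenextract.hsp`** — Hansen solubility parameters: total parameter,
  Hansen distance (factor-4 dispersion weighting), relative energy difference
  (RED), inversion of RED panels into solute solubility spheres, evaporation
  energy and solvent-screening reports.
* **`greenextract.kinetics`** — sphere-diffusion extraction kinetics: forward
  series profile, fitting of effective diffusivity `Deff` and starting
  accessibility `X0`, sampling-withdrawal mass-balance correction, multi-wash
  percolation simulation with retained-miscella carry-over, and industrial
  residual-oil extrapolation.
* **`greenextract.energy`** — the crushing-process energy/steam ledger:
  preparation, desolventization, distillation, desolventizer heat recovery
  and losses, per-step heat (MJ/t) and steam (kg/t), plus scenario comparison.
* **`greenextract.economics`** — EUR/t cost-benefit balance of the
  substitution (solvent make-up, extra steam, oil/cake mass shift,
  fixed-cost reduction).
* **`greenextract.composition`** — fatty-acid label parsing and
  SFA/MUFA/PUFA class sums, sterol tables, alpha-tocopherol-equivalent
  vitamin-E activity, Welch-test profile comparison from summary statistics.
* **`greenextract.synthetic`** — deterministic generators emulating the bench
  data: kinetic runs with per-draw withdrawal bookkeeping and noise models,
  replicate composition tables, RED panels from known spheres.
* **`greenextract.datasets`** — packaged reference tables (solvent
  properties, RED panel, fatty-acid/sterol/tocopherol compositions) and
  default YAML configurations, all plain CSV/YAML under
  `src/greenextract/data/`.

## Command line

```bash
greenextract --help
greenextract hsp fit-sphere                     # invert the packaged RED panel
greenextract hsp screen                         # ranked solvent table
greenextract synth kinetics --solvent methf --seed 1 --out k.csv
greenextract kinetics fit --input k.csv --t0 5
greenextract kinetics washes                    # percolation wash simulation
greenextract energy --scenario hexane --scenario methf --compare
greenextract econ
greenextract compo summarize --input src/greenextract/data/fatty_acids_methf.csv
greenextract report --out-dir report --seed 1   # full pipeline bundle
```

`greenextract report` chains every stage on the packaged fixtures and writes
per-stage CSVs plus a combined `report.md`; identical config and seed give
byte-identical outputs.

## Notes on the packaged fixtures

* Two solvent Hansen tables are shipped on purpose: the panel-native set
  (`solvents.csv`, hexane dispersion 14.0) and the property-sheet-converted
  set (`solvents_cal_converted.csv`, hexane 14.93). They disagree and are
  never merged. Sphere inversion uses `solvents_sphere_fit.csv` (hexane
  14.9), the only coordinates geometrically consistent with the packaged RED
  panel.
* The energy-scenario YAMLs carry a few constants (preparation heats,
  miscella-heating heat, condensed-steam allowance) that are inherited from
  the source balance rather than recomputed; the module docstrings say which
  and why.
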