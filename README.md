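# cochperm

Water permeability of the cochlear perilymph–endolymph barrier, as a
tested, reusable pipeline: surface-area morphometry of the barrier
partitions, a 1-D tracer-dispersal simulator for the three coupled
cochlear scalae, two-exponential uptake-kinetics fitting, closed-form
diffusional/osmotic permeability arithmetic, and a seeded synthetic-data
generator so every stage runs offline.

## Layout

| module | what it does |
| --- | --- |
| `cochperm.morphometry` | trapezoidal per-half-turn areas of Reissner's membrane and the organ of Corti, replicate statistics, outer-sulcus-cell shunt area |
| `cochperm.fluids` | diffusion + perfusion advection + first-order scala–scala/scala–blood exchange on 1-D scala grids; mass-balance accounting; half-time calibration by bisection |
| `cochperm.kinetics` | the two-exponential endolymph uptake model, its evaluation (with a guarded series form near the `alpha = P''` pole) and bounded least-squares fitting |
| `cochperm.permeability` | `P_D = P' V_e / A`, `J_v = V_e (SI/100)/duration`, `P_f = J_v/(Vw A dc)`, `P_f/P_D` ratios, reference means, channel-density estimate |
| `cochperm.synthetic` | seeded generators for morphometry tables, replicate sets and in-vivo-style observation records (ground truth serialised alongside) |
| `cochperm.pipeline` / `cochperm.cli` | scenario orchestration (`SV+ST/SM`, `SV/SM`, `ST/SM`, `osmotic-CDE`, `osmotic-OSC`) and report rendering |

Packaged data (`src/cochperm/data/`): a calibrated guinea-pig half-turn
width/length fixture, the three tracer scenario configurations, the
osmotic parameter sheet and a comparative table of epithelial
permeability coefficients.

## CLI

```sh
cochperm areas --out areas.json                      # barrier areas from the fixture table
cochperm simulate --config SV+ST/SM --out-csv tc.csv --out-meta meta.json
cochperm fit --timecourse tc_sm.csv --out fit.json   # time_min,concentration_pct columns
cochperm perm --outdir perm/                         # osmotic scenarios + reference table
cochperm synth --what observations --scenario osmotic --seed 1 --out obs.json
cochperm pipeline --scenario SV/SM --outdir run/     # full stage chain
cochperm report --run-dir run/
```

Exit codes: 0 success, 2 validation error, 3 numerical failure.

## Notes

- The half-turn fixture is an approximation with a smooth base-to-apex
  width trend, calibrated so the partition totals equal the published
  11.46 / 9.78 mm²; it is a fixture, not digitised source data.
- The channel-density quotient from the published inputs is
  3.14 × 10⁴ µm⁻², not the published 3.45 × 10⁴ µm⁻²; the computed
  value is reported and the difference documented in the result object.
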