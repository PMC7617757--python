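# oxyregulon

Single-cell analysis of the *E. coli* OxyR oxidative-stress regulon:
a mechanistic ODE model of the H2O2 response, a seeded synthetic
mother-machine track generator with planted ground truth, the
growth-corrected trace statistics used on such data, and the rank-test
classification of promoters into regulation categories.

## The problem

Under sudden H2O2 stress, *E. coli* transiently stops growing. Because a
protein's concentration balances synthesis against growth dilution, the
arrest alone makes *every* gene's expression level pulse upward — even
repressed ones. Disentangling true transcriptional regulation from this
passive, genome-wide pulse requires the growth-corrected **promoter
activity**

    (1/A) d(I·A)/dt = I·(1/A)(dA/dt) + dI/dt,

where `I` is a cell's mean reporter fluorescence and `A` its area, with
`(1/A)(dA/dt)` taken as the instantaneous elongation rate
`(log L_t − log L_{t−Δt})/Δt`. On activity, regulon promoters fall into
five classes — sustained or transient up/down, or unchanged — and the
sustained-upregulated genes further split into **pulsatile** (peak/steady
level ratio ≈ 3, peaking 25.7 ± 4.7 min after treatment) and **gradual**
(ratio ≈ 1.5, peaking at 37.5 ± 7.8 min) dynamics.

The model couples the OxyR redox switch to growth and scavenging:
intracellular H2O2 (influx `R_influx·[H2O2]_ext`, Michaelis–Menten removal
by AhpC and KatG) oxidises OxyR; oxidised OxyR induces promoters with
occupancy `ox/(ox + K_D)` at signed maximal rate `K_ind`; GrxA re-reduces
OxyR; growth follows a Hill inhibition `g(H) = g_max·K_g^n/(K_g^n + H^n)`
and dilutes everything, including plasmid copy number (`dn/dt = R_n − g·n`).
A single parameter — the OxyR–promoter dissociation constant `K_D` —
moves a reporter between gradual and pulsatile regimes, and per-cell
attenuation of the external dose along a trench (`(1−a)^k`, a ≈ 0.3)
generates the spatial expression gradients. See `docs/methods.md` for the
full equations, parameter table and design choices.

## Worked example

Classify a synthetic 31-promoter regulon (planted ground truth: 11
sustained up, 2 transient up, 8 sustained down, 7 transient down, 3
unchanged; ~2500 frontier-cell tracks per gene) from growth-corrected
promoter activity:

```bash
oxyregulon run-all --config examples/planted_regulon.yaml --out runs/demo
```

prints (seed 7, ~30 s):

```json
{
  "category_counts": {
    "none": 2,
    "sustained_down": 9,
    "sustained_up": 11,
    "transient_down": 7,
    "transient_up": 2
  },
  "n_genes": 31,
  "transient_total": 9
}
```

Thirty of the 31 planted categories are recovered; one "none" gene is
called sustained-down — the expected cost of fifteen exact-null
Mann-Whitney tests at α = 0.05, which no amount of data removes
(`docs/methods.md`, "Classification"). The run directory holds the track
table, the per-cell activity units, the per-gene report
(`report.tsv`: direction, persistence, p-values, category) and
`summary.json` above; re-running with the same seed reproduces every
output byte for byte.

The mechanistic counterpart runs the ODE panel instead:

```bash
oxyregulon run-all --config examples/mechanistic_demo.yaml --out runs/mech
```

labels the high-`K_D` reporter pulsatile (activity peak/steady regression
slope 3.67 across 25/50/100 µM) and the low-`K_D` reporter gradual (0.80).

The same stages are available as a library
(`oxyregulon.model.simulate`, `oxyregulon.synthetic.generate_regulon`,
`oxyregulon.metrics.promoter_activity`, `oxyregulon.classify.classify_dataset`)
and as standalone subcommands (`generate`, `simulate`, `metrics`,
`classify`, `validate`).

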