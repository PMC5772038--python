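# memdiffkit

Analysis toolkit for two linked questions in yeast membrane physiology:

1. **How do membrane-partitioning alcohols (ethanol, n-butanol) change the
   physical state of a lipid bilayer?**  Given particle ensembles of a model
   plasma membrane (DOPC, POPI, the sphingolipid IPC and ergosterol), the
   package computes the standard bilayer metrics from density profiles along
   the membrane normal: area per lipid, phosphate-peak thickness d_PP,
   deuterium order parameters S_CD = ⟨(3 cos²θ − 1)/2⟩, the number of waters
   in the membrane interior (where the acyl-tail density exceeds the water
   density), alcohol partitioning between bulk and membrane (bulk = where
   water density exceeds phosphate density) and alcohol insertion depth
   relative to the POPI glycerol backbone.  Uncertainties are 95% intervals
   from a 100-sample frame bootstrap (intercept/peak metrics) or block
   averaging (box and order metrics).

2. **How fast does a weak acid enter the cell, and what does the
   accumulation imply about intracellular pH?**  Radiotracer (¹⁴C-acetic
   acid) uptake assays are analysed from scintillation counts through a
   standards calibration, blank/background correction, intracellular
   concentration (cell volume 2 µL/mg dry weight), accumulation fold
   A = c_in/c_out, and the Henderson–Hasselbalch equilibrium relation

   ```
   pH_i = pKa + log10(A / f_out − 1),    f_out = 1 / (1 + 10^(pH_out − pKa))
   ```

   plus initial diffusion rates (zero-intercept early-time slopes),
   per-condition diffusion constants, Welch t-test condition comparisons,
   and growth-curve metrics (µ_max, time to glucose depletion).

Every stage is testable without external data: `memdiffkit.synth` generates
bilayer ensembles, uptake time courses and growth curves with known ground
truth recorded alongside the data.

## Worked example

Generate a synthetic n-butanol-loaded bilayer (100 frames, 90% of 160
butanol molecules in the head-group layer, 40 interior waters per frame on
average) and compute the metric bundle:

```bash
cat > spec.yaml <<EOF
n_frames: 100
n_water: 1200
interior_water_target: 40
alcohol: {species: BUTANOL, n_molecules: 160, membrane_fraction: 0.9, hydroxyl_depth: 0.03}
EOF
memdiffkit synth bilayer --spec spec.yaml --seed 7 --out run
memdiffkit metrics --input run/ens.tsv --seed 7 --out report
```

`report/metrics.tsv` (abridged):

```
metric                              value         lower         upper         method  n
area_per_lipid_nm2                  0.529930881   0.5277120647  0.5321496974  block   5
thickness_nm                        3.786146905   3.768415961   3.803877849   block   5
scd_chain_mean                      0.1248382839  0.1246274633  0.1250491045  block   5
interior_water_count                40.03         39.00475      41.0205       bootstrap 100
partition_percent_butanol           89.81875      89.34609375   90.37921875   bootstrap 100
depth_terminal_methyl_butanol_nm    0.3909189556  0.3573495278  0.4804815509  bootstrap 100
```

Each 95% interval covers its generating value: the ensemble was built with
an area per lipid of 0.53 nm², phosphate peaks at ±1.9 nm (thickness
3.8 nm), mean chain order 0.125, 40 interior waters, 90% membrane
partitioning and a terminal-methyl depth of 0.40 nm.

The uptake pipeline works the same way:

```bash
memdiffkit synth uptake --seed 7 --out assay
memdiffkit uptake --samples assay/samples.tsv --standards assay/standards.tsv \
    --assay assay/assay.json --out assay_report
```

which prints a plateau of 18.5 mM intracellular acetate for 2 mM external
acid — an accumulation fold of 9.3 (generated: 9.0), a first-order rate
constant of 0.0099 s⁻¹ (generated: 0.01) and an intracellular pH of 6.2:
the cytosol is nearly 1.5 pH units above the pH-5 buffer, which is exactly
why the acid keeps flowing in until the accumulated anion equilibrates.

## Layout

| module | contents |
| --- | --- |
| `memdiffkit.particles` | particle/ensemble data model, labelled-table and multi-frame GRO I/O, role mapping, report writer |
| `memdiffkit.profiles`  | density profiles, peak location, profile intercepts, bootstrap and block-averaging intervals |
| `memdiffkit.membrane`  | area per lipid, thickness, S_CD, interior water, partitioning, insertion depth, composition arithmetic |
| `memdiffkit.uptake`    | scintillation calibration, concentrations, pH inference, diffusion kinetics, condition comparison |
| `memdiffkit.growth`    | maximum specific growth rate, diauxic-shift timing |
| `memdiffkit.synth`     | ground-truth generators for all of the above |
| `memdiffkit.cli`       | `memdiffkit` command: `synth`, `metrics`, `profile`, `uptake`, `growth`, `report` |

See `docs/methods.md` for the statistical conventions, generator design and
known limitations.
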