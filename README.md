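# sarcoquant

Quantification pipeline for graded titin-cleavage experiments in skeletal
muscle fibers: sarcomere ultrastructure, label distributions, fiber
mechanics, nanoindentation and gel densitometry — plus synthetic-data
generators that provide ground-truth-labelled inputs for every stage.

## What it does

| Module | Purpose |
| --- | --- |
| `sarcoquant.synthetic` | Generators for striated EM micrographs (controllable Z-disk waviness / orientation jitter), immunogold particle fields with epitope offsets and recoil mixtures, generalized-Maxwell ramp-hold force traces, Hertz indentation curves, and multi-band gel lanes. Every generator records exact ground truth and is bit-reproducible under a fixed seed. |
| `sarcoquant.fracture` | Z-disk disorder score ("fracture area", nm²): ridge segmentation → orthogonal line fits → residuals weighted by inter-line angular differences, length-weighted average. |
| `sarcoquant.labels` | Gold-particle detection (8 nm inclusion gate, fused-aggregate splitting), I-band ROI filtering, nearest-Z-disk epitope distances with a two-component mixture readout, per-sarcomere counts, thick-filament end-to-end lengths, HaloTag/ACTN2 intensity ratios. |
| `sarcoquant.mechanics` | Ramp-hold protocol segmentation, elastic/viscous decomposition, time-matched treatment/control timecourse normalization, force-vs-intact-titin regression, active force drop. |
| `sarcoquant.afm` | Contact-point detection and spherical Hertz fitting (Young's modulus, indentation depth at the trigger force), grouped summaries. |
| `sarcoquant.gel` | Lane profile extraction, rolling-minimum baseline, band areas, percent cleaved titin, MyHC/titin/NEB ratios. |
| `sarcoquant.balance` | Order-of-magnitude thick-filament centering force balance. |
| `sarcoquant.pipeline` | YAML-config-driven orchestration with provenance logging. |

## CLI

Everything is reachable through the `sarcoquant` entry point:

```bash
# generate synthetic inputs
sarcoquant simulate em  --seed 1 --out out/em
sarcoquant simulate iem --epitope N2A --out out/iem
sarcoquant simulate afm --e-kpa 4.81 --out out/afm
sarcoquant simulate gel --cleaved-fraction 0.4312 --out out/gel

# analyses
sarcoquant fracture score out/em/em.tiff --out out/frac --overlay
sarcoquant labels detect out/iem/iem.tiff --out out/particles.csv
sarcoquant labels distances out/particles.csv --geometry out/iem/iem_geometry.json --out out/dist.json
sarcoquant mech decompose trace.csv --out summary.csv
sarcoquant afm fit out/afm/afm_curve.csv
sarcoquant gel quantify out/gel/lane.csv --bands bands.yaml
sarcoquant balance --displacement-nm 35

# whole pipelines from a config file
sarcoquant run config.yaml
```

A pipeline config is a YAML dict with `seed`, `outdir` and an ordered
`stages` list (`simulate_em`, `fracture_score`, `simulate_trace`,
`simulate_afm`, `afm_fit`, `simulate_gel`, `gel_quantify`, `balance`);
replaying the same config and seed reproduces byte-identical outputs.

## File formats

Micrographs are 16-bit grayscale TIFF with the pixel size in the
resolution tags (px/cm) and optional JSON truth sidecars; force traces are
CSV (`time_s, sl_um, force`), indentation curves CSV
(`position_nm, force_nn`), lane profiles CSV (`position, intensity`).
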