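# rsnvar

Test–retest variability of resting-state networks on parcellated BOLD
data: single-subject spatial ICA, component fingerprints and
neuronal/non-neuronal classification, template matching across nine
canonical networks (auditory, DMN, ECNL, ECNR, salience, sensorimotor,
VL, VM, VO), graph-strength maps from z-map-derived edge weights, the
ratio-of-fit (ROF) variability statistic with best-acquisition
selection, and regional PET–connectivity coupling. A synthetic-data
module generates sessions with known ground truth so every stage is
testable without external scans.

## Method summary

1. **Parcellation** — voxel images are reduced to region means over a
   label atlas; all analysis operates on T×N tables.
2. **Motion** — mean displacement Δ (time-averaged 6-parameter norm,
   mm and deg summed in quadrature) and displacement speed Σ (norm of
   per-TR parameter changes); motion curves are regressed out of the
   region series before ICA.
3. **ICA + fingerprint** — spatial ICA (k components, default 30);
   each component gets an 11-D fingerprint (degree of clustering,
   spatial skewness/kurtosis/entropy, one-lag autocorrelation, temporal
   entropy, power fractions in 5 bands up to 0.25 Hz). Components are
   neuronal when 0.01–0.05 Hz power dominates 0.1–0.25 Hz power.
4. **Network assignment** — greedy exclusive matching of the nine
   templates to components by goodness-of-fit (mean z inside minus
   outside the template), all networks considered simultaneously.
5. **Graph strength** — edge weights `w_ij = |z_i| + |z_j| − |z_i − z_j|`,
   normalized to [0, 1], averaged over the 101 thresholds 0…1 (step
   0.01), row-summed into node strengths.
6. **ROF** — regions with strength above half the network maximum are
   compared to the template mask:
   `ROF = (in − out) / mask size`; test–retest variability is
   ΔROF = ROF(T1) − ROF(T2) with missing acquisitions contributing 0,
   summarized as mean |ΔROF| over the nine networks.
7. **PET coupling** — per-region max strength over neuronal networks,
   z-scored and correlated with the (z-scored) PET map; two-sided p
   from the t-transform with N−2 degrees of freedom.

## CLI

```sh
rsnvar simulate --out patient/ --seed 3            # synthetic fixture
rsnvar analyze --fixture patient/ --out reports/ --seed 1 --k 12
rsnvar analyze --config analysis.yaml   # same keys: fixture/out/seed/k
rsnvar table1-check                                # reference table audit
rsnvar petcorr reports/gs.tsv --pet patient/pet.tsv
rsnvar motion-qc patient/motion_T1.tsv
```

Exit codes: 0 ok, 1 validation/configuration error, 2 runtime failure.

A fixture directory contains: `atlas_labels.nii`, `atlas_labels.tsv`
(`region_id`, `name`), `atlas_templates.tsv` (`network`, `region_id`),
`series_T1.tsv` / `series_T2.tsv` (one row per time point, one column
per region id), `motion_T1.tsv` / `motion_T2.tsv` (TraX…RotZ), `pet.tsv`
(`region_id`, `uptake`) and a `truth.json` sidecar (config, seed,
ground-truth membership).

`analyze` writes `rof_table.tsv` (per-network In/Out/ROF per acquisition
plus ΔROF), `variability.json` (ΔROF, mean |ΔROF|, best acquisition,
percent neuronal), `coupling_best.json` / `coupling_concat.json`,
`qc_T1.json` / `qc_T2.json`, and `run_log.json`; every report embeds
the seed and a config hash.

## Conventions fixed by this implementation

Several conventions the source material leaves open are pinned down and
covered by tests: missing acquisitions contribute 0 to ΔROF and the
mean uses the fixed nine-network denominator (validated against the
reference table); edge weights are normalized per component by the
matrix maximum; threshold ties are kept (≥); z-scores use the sample
(n−1) standard deviation; skewness is the bias-uncorrected moment;
rotations enter the motion norms in degrees unless conversion is
requested.
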