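# ebmorph

Quantitative analysis of 3D embryoid-body (EB) differentiation: volumetric
morphometry of the three-zone EB archetype, proliferation-domain accounting
from confocal-like stacks, marker-intensity profiling, qPCR expression
analysis, cohort statistics, and a French-flag morphogen-threshold model of
patterning and scaling invariance.

## The problem

Pluripotent stem cells aggregated in suspension differentiate into embryoid
bodies with a stereotyped radial architecture: an outer shell of
extraembryonic endoderm (ExEn, Gata4⁺), an inner epiblast-like layer
(Epi-l, Oct4⁺), and a central cavity formed by apoptosis and hollowing.
Quantifying this architecture means turning routine measurements —
bright-field diameters, Hoechst/EdU confocal stacks, Oct4/Gata4 sections,
qPCR Ct tables — into volumes, volume fractions, proliferation indices,
fold changes, and cohort statistics, and asking whether the pattern
proportions scale with EB size.

`ebmorph` implements that pipeline as a library with a thin CLI. Because
such raw data are usually lab-internal, a first-class synthetic-data module
generates every input with planted ground truth, so the whole chain is
testable end-to-end.

## The core quantities

- **Volumes.** EBs are near-spherical (circularity/roundness ≈ 0.9), so an
  EB measured in 2–8 directions gets volume V = πd̄³/6 from the mean
  diameter d̄. Growth is the ratio of stage mean volumes; cohort
  variability is CV% = 100·s/d̄ (sample sd).
- **Pattern proportions.** For concentric zones, the cavity fraction is
  (d_cav/d)³, the ExEn fraction 1 − ((d − 2t)/d)³ for shell thickness t,
  and Epi-l the remainder; the three sum to 1.
- **Proliferation index.** Per plane, nuclei are segmented (Otsu threshold
  → distance-transform watershed → inclusive 15–350 µm² area filter) in
  both channels; the EdU percentage is 100·N_EdU/N_nuclei, averaged over
  planes.
- **Expression.** Relative expression by the comparative method:
  ΔCt = Ct(target) − Ct(Hprt), ΔΔCt = ΔCt − ΔCt(reference sample),
  fold = 2^−ΔΔCt; profiles of averaged ΔCt are z-scored per gene and
  clustered hierarchically with Euclidean distances.
- **French-flag model.** A morphogen at boundary concentration c_s diffuses
  into a sphere of radius R with first-order uptake; at steady state
  c(r) = c_s (R/r) sinh(r/λ)/sinh(R/λ) with diffusion length λ = √(D/k).
  Thresholds T1 > T2 > T3 assign fates: ExEn where c ≥ T1, Epi-l where
  T2 ≤ c < T1, cavity where c < T2. Since c depends only on r/R and R/λ,
  proportions are exactly invariant under (R, λ) → (aR, aλ) — the model's
  statement of size-invariant patterning.

## Worked example

```sh
$ ebmorph simulate --seed 1 --out demo        # synthetic cohort, stack, section, Ct table
$ ebmorph measure demo/diameters.csv --out demo/summary.csv
EB10/EB1 volume ratio: 14.33 (rounds to 14)
$ ebmorph count demo/stack.tiff
EdU-labelled: 75.0% (mean over 5 planes)
$ ebmorph profile demo/section.tiff --out demo/profile.csv
cavity_d=388.5 µm  epil_outer_d=519.0 µm  total_d=599.0 µm
$ ebmorph frenchflag --radius 300 --lam 100 --t1 0.84 --t2 0.53
r1=273.5 µm  r2=195.4 µm
ExEn 24.2%  Epi-l 48.1%  cavity 27.6%
```

The simulated day-1 → day-10 cohort was planted with a diameter growth
factor of 2.41, i.e. a 14-fold volume increase, and the measured ratio
rounds back to 14. The stack was planted with 75% EdU-labelled nuclei and
the segmentation recovers 75.0%. The section was planted with a cavity at
0.646 of the total diameter (≈ 27% by volume) and an ExEn shell; the
measured diameters reproduce that geometry. The morphogen model with
R/λ = 3 and thresholds at 0.84 and 0.53 of the boundary concentration
yields archetype-like proportions (≈ 24/48/28%), identical at every EB
size when λ scales with R (`--sizes 100,200,400` prints the scaling table).

`ebmorph report --seed 1 --out results/` runs every stage and writes CSV
tables, plots, and a deterministic `summary.json` carrying the seed and a
config hash.

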