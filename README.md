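# mtintegrity

Quantification of cortical microtubule integrity in fluorescence
micrographs of plant cells, with a synthetic confocal-image generator, the
post-hoc statistics of a dose–response bioassay, and the regression that
links early microtubule loss to later cell death.

## The problem

Plant cells expressing GFP-tagged α-tubulin show their cortical microtubule
array in vivo: numerous, mostly parallel bundles lying beneath the plasma
membrane. Anti-microtubular compounds (herbicides such as oryzalin, or
bioactive plant extracts) disassemble these bundles; the released tubulin
dimers fluoresce as a diffuse "soluble" background. Screening such
compounds needs a per-cell scalar that tracks this transition in an
operator-independent way.

The score used here works on intensity profiles sampled parallel to the
cell's elongation axis, perpendicular to the transverse microtubule
bundles, which appear as peaks separated by darker troughs. For a profile
I(x):

1. first derivative (forward difference): ΔI(x) = I(x+1) − I(x) — positive
   on the rising flank of each crossed bundle, negative on the trailing
   flank;
2. noise filter: sliding sum of k consecutive derivative values (default
   k = 2), which cancels the alternating single-pixel signal of
   photomultiplier noise while genuine flank pairs survive;
3. normalised spread: S = 100 · SD(filtered derivative) / max I, where the
   division by the profile maximum cancels laser/gain differences between
   acquisitions.

A cell's score is the mean over several parallel profiles. On the
conventional scale, an intact array scores ≈ 60 and a completely
eliminated one ≈ 30; the package's synthetic generator and default
protocol are calibrated to exactly these anchors.

Because the original micrograph collections of such assays are rarely
deposited, the package includes a first-class synthetic-image module: it
renders PSF-blurred filament arrays over a granular cytoplasmic background
with organelle-shaped dark voids, Poisson shot noise and Gaussian read
noise, and a single *disintegration* parameter d ∈ [0, 1] that moves the
photon budget from filaments to soluble background (conserving the total).
Downstream, treatment groups are compared with Duncan's multiple range
test (compact letter display), dose–response tables report the effect
onset and saturation doses, and a binomial Evans-blue mortality model
couples integrity to cytotoxicity.

## Worked example

```python
import mtintegrity as mt

# one intact and one fully disintegrated synthetic cell, same seed
params = mt.SyntheticParams()                       # packaged calibration
intact = mt.generate_cell_image(params.replace(seed=33))
gone   = mt.generate_cell_image(params.replace(seed=33, disintegration=1.0))
print(mt.score_cell(intact).value, mt.score_cell(gone).value)

# the full synthetic experiment: 12 conditions (3 tissues x 2 sites x
# 2 doses), 15 cells each, Duncan letters, mortality regression
report = mt.run_synthetic_experiment(mt.default_config(seed=5))
print(report.regression.summary())
```

prints (seed 5):

```
62.41796909388252 26.579500183314007
mortality[%] = 169.81 -2.243 * score  (R^2 = 0.726, n = 12; slope SE = 0.435)
```

The first line shows the two calibration anchors at the single-cell level
(≈ 60 intact, ≈ 30 eliminated). The regression line says that each lost
score unit raises mortality three days later by ≈ 2.2 percentage points,
and that integrity at 2 h explains ≈ 73 % of the variance in mortality —
microtubule status is a good early predictor of cytotoxicity. The report
also carries the per-cell score table, the per-condition summary with
Duncan letters, and tissue × site heat-map matrices whose colour anchors
are 30 (eliminated) and 60 (intact).

The same pipeline is scriptable from the shell:

```sh
mtintegrity simulate --out-dir imgs --n-images 10 --seed 4 -d 0.5
mtintegrity score --images imgs --manifest imgs/manifest.csv --out scores.csv
mtintegrity run-all --out-dir results --seed 5
```

## Layout

* `src/mtintegrity/synthetic.py` — image generator, dose→disintegration
  map, mortality coupling
* `src/mtintegrity/scoring.py` — profiles, derivative filter, score
* `src/mtintegrity/groups.py` — Duncan MRT, dose–response, heat maps
* `src/mtintegrity/mortality.py` — mortality fractions, OLS linkage
* `src/mtintegrity/pipeline.py`, `cli.py`, `config.py`, `io.py` —
  orchestration, command line, frozen defaults, TIFF/CSV I/O
* `docs/methods.md` — model assumptions, calibration and limitations
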