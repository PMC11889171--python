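# fibdamage

Quantitative profiling of focused-ion-beam (FIB) milling damage in cryo-ET
lamellae using subtomogram-averaging B-factor analysis.

## The problem

Cryo-electron tomography of cells requires thinning frozen samples into
~100–300 nm lamellae with a (plasma) focused ion beam. The ion collision
cascade damages a layer of material beneath each milled surface, and high-
current trench milling can additionally leave an amorphous, feature-free
region on the lamella backside. Structural biologists need to know how deep
that damage reaches, because particles inside the damaged layer degrade the
resolution of subtomogram averages.

`fibdamage` implements the damage-profiling analysis for particle data from
such lamellae:

- **Surface geometry** — interpolate sparse manual annotations of the two
  milling surfaces into triangulated boundary sheets and compute each
  particle's shortest 3-D distance to the nearer surface ("depth"), plus
  local lamella thickness.
- **Cohorts** — group particles into half-open 5 nm depth bins (0–60 nm)
  or 1 µm backside-distance bins, and draw **tomogram-matched controls**:
  equal numbers of particles per tomogram, randomly taken farther from the
  milling surfaces, to control for per-tomogram confounders (thickness,
  alignment quality, motion).
- **B-factors** — Rosenthal–Henderson estimation: for each cohort, random
  subsets of halving size are "refined" and the line
  `1/resolution² = m·ln(N) + c` is fitted by pooled OLS over three repeats;
  the B-factor is `B = 2/m` with `σ_B = 2σ_m/m²`.
- **Damage curves** — per-bin B-factor ratios (cohort/control) and
  extrapolated resolution differences at 5000 particles, each with closed-
  form error propagation, fitted with a weighted three-parameter exponential
  decay `y = A·e^(−kx) + c`.
- **FSC** — Fourier shell correlation between half maps with resolution at
  the 0.143 criterion, capped at Nyquist (2 × voxel size).
- **Synthetic data** — a generator producing slab lamella geometry,
  uniformly placed particles, annotations, and resolution series from a
  ground-truth exponential damage model, so the full pipeline is testable
  without any microscope data.

## Worked example

The package bundles the per-cohort B-factor tables of a published xenon
plasma FIB study of the *E. coli* 70S ribosome as reference inputs.
Reconstructing the damage curves from the printed depth table (slope from
each row's B-factor, intercept anchored at its printed particle count and
global resolution, extrapolation of each bin and its matched control to
5000 particles):

```bash
$ fibdamage worked-examples tables --out report/
dres decay: y = 17.8 exp(-0.1662 x) + 0.0192 (R^2 = 0.984); backside B range 284-321 A^2
```

The extrapolated-resolution difference decays with depth at
k ≈ 0.166 nm⁻¹ (decay length ≈ 6 nm) — damage is severe within ~10 nm of
the milling surface, negligible beyond ~30–45 nm — and the backside bins
show B-factors confined to 284–321 Å² with no significant rank trend
(Spearman r ≈ −0.31, exact p ≈ 0.61 on the rounded table values): no
detectable damage gradient at the micron scale behind the amorphous layer.

The same pipeline runs end-to-end on synthetic data with known ground
truth (here λ = 5.4 nm, i.e. k = 0.185 nm⁻¹):

```bash
$ fibdamage simulate bundle --out bundle/ --seed 1 --n-tomograms 12 --particles-per-tomogram 4200
$ fibdamage profile depth --bundle bundle/ --out report/
dres decay: y = 5.54 exp(-0.1672 x) + 0.00332 (R^2 = 0.999)
```

Reports are plain CSV/JSON (per-bin B ± SE tables, damage-curve points,
decay-fit parameters, seeds), with optional PNG plots.

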