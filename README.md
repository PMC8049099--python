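# mrsep

Separating metabolite and macromolecule (MM) signals in short-echo-time
proton MR spectroscopic imaging (¹H-MRSI), using learned component-specific
low-dimensional representations as reconstruction priors.

## The problem

Short-TE ¹H-MRSI preserves rapidly decaying signals, which is exactly why
its spectra contain both the metabolite resonances of interest (NAA, Cr,
Cho, Glu, Gln, mI, GABA, GSH, Lac) and broad macromolecule resonances that
overlap them across the whole spectrum. Quantifying metabolites — and using
the MM signal itself as a biomarker — requires separating the two
components from their sum, an ill-posed problem. The classic remedy, direct
parametric fitting of every voxel (often with early-FID truncation and
metabolite back-extrapolation), is sensitive to noise and model mismatch
and produces spatially erratic molecular maps.

## The method

Both components follow a parametric FID model

    rho(t) = Σ_m c_m e^{i(φ0+φ_m)} v_m(t) e^{-t/T2*_m + i2π δf_m t}
           + Σ_l b_l e^{i(φ0+ψ_l)} e^{-t²π²W_l²/(4 ln 2) + i2π δf_l t},

so each component lives on its own low-dimensional nonlinear manifold.
`mrsep` learns those manifolds with two deep autoencoders
(2T–1000–250–100–L–100–250–1000–2T, linear bottleneck) trained on synthetic
spectra with a mixed objective: reconstruct your own component, output zero
on the other. The learned networks N_met, N_mm then act as separation
priors in a constrained spatiospectral reconstruction

    min ‖d − Ω{F B⊙(X_met+X_mm)}‖² + λ1 Σ‖N_met(X_met^n)−X_met^n‖²
        + λ2 Σ‖N_mm(X_mm^n)−X_mm^n‖² + λ3 ‖D_w(X_met+X_mm)‖²_F

solved by ADMM (voxelwise network-regularized solves + a conjugate-gradient
linear step + multiplier update). A numerical brain phantom, a direct
parametric fitting baseline, and molecular-map extraction complete the
simulation pipeline. See `docs/methods.md` for the full model description
and design choices.

## Worked example

```python
import numpy as np
from mrsep import (SpectralAxis, build_default_basis, default_distributions,
                   generate_training_set, train_dae, TrainConfig)

axis = SpectralAxis(n_points=512, bandwidth=2000.0)   # 3 T, 2000 Hz, T=512
basis = build_default_basis(axis)                     # 9-metabolite analytic basis
dists = default_distributions()

met = generate_training_set(4000, "metabolite", dists, basis, axis, rng_seed=7)
mm = generate_training_set(4000, "macromolecule", dists, None, axis, rng_seed=7)

cfg = TrainConfig(batch_size=250, epochs=40, seed=7)
met_dae = train_dae(met, mm, model_order=24, cfg=cfg)
print(f"held-out metabolite error: {met_dae.final_test_error:.3f}")

x_mm = mm.samples[-500:].astype(np.float32)
ratio = np.linalg.norm(met_dae.net(x_mm)) / np.linalg.norm(x_mm)
print(f"MM pass-through of the metabolite DAE: {ratio:.3f}")
```

Output from this exact snippet:

```
held-out metabolite error: 0.308
MM pass-through of the metabolite DAE: 0.014
```

The first number is the relative ℓ2 approximation error on unseen
metabolite spectra (a quick 40-epoch run; the desk-scale profile in the
experiments trains longer on more data and reaches ~15%). The second is
the key separation property: the metabolite network passes through only
~1% of macromolecule signal energy.

The end-to-end simulation studies are exposed both as library calls
(`mrsep.experiments`) and a CLI:

```bash
mrsep gen-basis --out basis.h5
mrsep phantom --nx 32 --ny 32 --snr 30 --seed 7 --out phantom.h5
mrsep run-experiment --study phantom --profile desk --seed 1 --out report.json
```

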