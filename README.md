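# sgpdeconv

Accelerated Poisson image deconvolution for fluorescence microscopy —
Richardson-Lucy (RL) and scaled-gradient-projection (SGP) solvers for
confocal (CLSM) and STED images, with parametric PSF models, boundary-effect
correction, and a synthetic microtubule-phantom simulator for controlled,
fully reproducible benchmarking.

## The problem

A fluorescence microscope records blurred, photon-limited images: counts
`y ~ Poisson(Hx + b)`, where `x` is the specimen's emission density, `H`
convolution with the point-spread function, and `b` a known background.
Maximum-likelihood deconvolution minimizes the generalized Kullback-Leibler
divergence

    f0(x) = Σᵢ [ yᵢ ln(yᵢ/(Hx+b)ᵢ) + (Hx+b)ᵢ − yᵢ ],   x ≥ 0,

(MAP adds a Tikhonov penalty ½β‖x‖²).  The classical solver is RL,
`x ← (x/H^T1) ⊙ H^T(y/(Hx+b))` — robust but slow, needing hundreds of
iterations.  Because the exact minimizers are spiky "night-sky" solutions,
iterations are stopped early, at the semiconvergence point where the
divergence from the (known, in simulation) ground truth is minimal.

SGP solves the same problems far faster: a diagonal scaling
`D = clip(x/(H^T1 + βV₁(x)), L₁, L₂)` (the RL/split-gradient scaling),
Barzilai-Borwein step lengths with adaptive alternation, projection onto
`x ≥ 0`, and a monotone Armijo line search.  On the synthetic benchmarks in
this package SGP reaches its optimal restoration in roughly 5× fewer
iterations than RL for confocal images and roughly 2× fewer for STED, at
matching restoration quality.  See `docs/methods.md` for the full model and
algorithmic details.

## Worked example

```python
import numpy as np
from sgpdeconv import (
    CONFOCAL, make_dataset, ImagingOperator, Objective,
    SGPConfig, sgp_deconvolve, rl_deconvolve,
)

# simulate a 256x256 confocal acquisition of a microtubule phantom at 13 dB
ds = make_dataset(CONFOCAL, size=256, phantom_seed=11, noise_seed=42)
print(f"SNR {ds.snr_db:.2f} dB, peak {ds.image.max()} counts")

op = ImagingOperator.from_kernel(ds.psf.normalized(), ds.image.shape)
objective = Objective("ml_kl", op, ds.image)
cfg = SGPConfig(stop_mode="kl_to_truth_min", max_iter=2000, kl_patience=50)

rl = rl_deconvolve(objective, cfg, ground_truth=ds.scaled_truth)
sgp = sgp_deconvolve(objective, cfg, ground_truth=ds.scaled_truth)
print(f"RL optimal iteration:  {rl.optimal_iteration}")
print(f"SGP optimal iteration: {sgp.optimal_iteration}")
```

prints (exactly reproducible from the seeds):

```
SNR 13.00 dB, peak 82 counts
RL optimal iteration:  483
SGP optimal iteration: 108
```

i.e. SGP needed 78% fewer iterations than RL to reach its best restoration
of this image.  Both solvers' restorations sit at closely matching KL
divergence from the ground truth.

The same pipeline is available from the shell:

```
sgpdeconv simulate --modality clsm --size 256 --snr-db 13 --seed 1 --out sim/
sgpdeconv deconvolve --image sim/image.tif --psf-kernel sim/psf.tif \
    --algorithm sgp --stop objective --tol 1e-3 --out restored/
sgpdeconv benchmark --size 256 --phantoms 10 --noise 2 --seed 1 --out bench/
```

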