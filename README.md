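# regstack

Rigid registration and frame accumulation for low-SNR transmission image
sequences, built around a hybrid **GA + constriction-factor PSO (GA-CPSO)**
optimizer.

## The problem

Weak-signal imaging (e.g. multispectral transmission imaging of thick
scattering tissue) produces sequences of dim, noisy frames.  Summing m
frames raises the signal-to-noise ratio by √m — but only if the frames are
aligned.  Hand-held acquisition and subject motion displace frames by small
rigid motions (translation tx, ty and rotation θ), and accumulating
misaligned frames produces ghosting instead of enhancement.

`regstack` estimates the rigid transform aligning each frame to a fixed
reference by minimising the mean-squared-error cost

```
MSE(p) = (1/n) Σ_i [ I_F(i) − I_M(T(i; p)) ]²,   p = (tx, ty, θ)
```

with a two-stage search:

1. **GA phase** — a real-coded genetic algorithm (population 50,
   roulette-wheel selection, one-point crossover p=0.8, Gaussian mutation
   p=0.05, 50 generations) performs the coarse global search;
2. **CPSO phase** — a particle swarm seeded at the GA's best refines it.
   Velocities are damped by the constriction factor
   χ = 2 / |2 − φ − √(φ² − 4φ)| with φ = c1 + c2 > 4; the **squared**
   constriction factor (χ², "SCF") contracts the swarm harder and reaches
   its final best in fewer iterations than the conventional factor.

Registration accuracy is scored in parameter space as
`A = 100 − (100/3)·(|X−x|/|X| + |Y−y|/|Y| + |R−r|/|R|)` percent, and image
quality before/after accumulation by correlation, mutual information, RMSE,
energy of gradient (EOG), Brenner gradient, gray level, standard deviation,
entropy and MMD.

Because real clinical sequences are not redistributable, the package ships a
synthetic phantom generator (smooth bright blob + textured interior +
high-contrast fiducials, known rigid jitter, additive Gaussian noise) that
serves as ground truth for every experiment.

## Worked example

```python
import numpy as np
from regstack import (RigidTransform, GAConfig, CPSOConfig,
                      apply_rigid_transform, mean_filter_4x4,
                      register_pair, registration_accuracy)
from regstack.phantom import PhantomSpec, make_sequence

# one noisy 256x256 phantom frame, denoised with the 4x4 mean filter
frame = mean_filter_4x4(make_sequence(PhantomSpec(), [RigidTransform()]).frames[0])

# displace it by a known rigid motion and register the original back
t_true = RigidTransform(25, -20, 5)
fixed = apply_rigid_transform(frame, t_true)
res = register_pair(fixed, frame, GAConfig(rng_seed=0), CPSOConfig(rng_seed=1))

print(res.transform)                                  # estimated (tx, ty, theta)
print(round(registration_accuracy(t_true, res.transform), 3))
```

prints

```
RigidTransform(tx=25.00000000000001, ty=-20.0, theta=4.999999999999999)
100.0
```

i.e. the hybrid recovers the 25 px / −20 px / 5° displacement to machine
precision (accuracy 100.000%); on noisier or independently noised pairs the
recovered accuracy drops into the 99.9% range.

The same machinery is available from the shell:

```bash
regstack phantom  --out demo --frames 20 --seed 0
regstack run      --frames demo/frames --out demo/out --seed 0
```

which writes denoised frames, per-frame transforms (`transforms.csv`), the
direct and registered accumulations, and a quality report comparing EOG,
Brenner, gray level, SD and entropy between the two.

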