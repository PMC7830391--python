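# acoct

Ant-colony hyperparameter tuning for total-variation-regularised few-view
X-ray CT reconstruction, with everything needed to run and validate the
pipeline end-to-end on synthetic data:

- **`acoct.geometry`** — scan geometries (2-D parallel/fan beam, 3-D cone
  beam) with an exact Siddon-style ray tracer providing a *matched*
  forward/back projector pair (sparse system matrices, exact adjoint) and
  the SART normalisation diagonals.
- **`acoct.phantoms`** — piecewise-constant thorax-like ellipse/ellipsoid
  phantoms (train/male/female variants) and a mixed Poisson–Gaussian
  photon-count noise model (default: 60 000 max photon count, Gaussian
  mean 0 / sd 0.5).
- **`acoct.recon`** — SART, OS-SART, CGLS, the adaptive-weighted TV (AwTV)
  norm and gradient, and the alternating data-fidelity / edge-preserving
  TV-descent solver (AwPCSD) with its five hyperparameters
  (ε, ng, β, β_red, δ), resumable state and literal stopping rules
  (β < 0.005; cosine < −0.99 with residual ≤ ε).
- **`acoct.metrics`** — correlation coefficient, universal quality index,
  relative 2-norm error, RMSE.
- **`acoct.aco`** — the ant-colony tuner: per-value pheromones
  (P_i = τ_i/Στ, update τ ← (1−σ)τ + mean score, max-normalised), one
  solver iteration per ant from the shared previous-iteration-best image,
  CC scoring, per-configuration accumulated-score ledger.
- **`acoct.cv`** — leave-one-angle-out cross-validation baseline (lowest
  mean held-out projection RMSE wins).
- **`acoct.harness`** — desk-scale comparison experiments: tuned vs
  arbitrary (ε = 700, ng = 100) vs CV vs CGLS, noise-level sweeps, angle
  arrangements, cross-sample transfer.

## CLI

```sh
acoct make-phantom --grid 64 --out phantom.nii
acoct simulate --phantom phantom.nii --geometry geom.yaml --seed 1 --out proj.tif
acoct reconstruct --projections proj.tif --geometry geom.yaml \
    --method awpcsd --params params.yaml --reference phantom.nii --out recon.nii
acoct tune-aco --projections proj.tif --geometry geom.yaml --reference phantom.nii \
    --ants 50 --generations 10 --iterations 50 --evaporation 1.0 --seed 1 --out tune/
acoct tune-cv --projections proj.tif --geometry geom.yaml --trial-stride 5 --out cv/
acoct run-experiment --plan plan.yaml --seed 1 --out exp/
```

Geometries, phantom specs, search spaces and experiment plans are plain
YAML/JSON mappings; volumes and projection stacks are NIfTI / multi-page
TIFF / `.npy` (projections carry a sidecar JSON with angles and noise
metadata).

## Notes on scale

The TV descent step is `η·s/‖s‖` with `η = k·dd(w)/dd(1)`; the step
constant `k` (default 1) is an absolute image-domain step length, so on
very small grids (≲ 32²) where the image L2 norm is below ~1, pass a
smaller `k` (e.g. 0.1) or pin `"k"` in a search-space `fixed` mapping.
The 64² default experiments work with `k = 1`.
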