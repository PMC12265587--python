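# spt-audit

How much of a widefield-fluorescence single-particle-tracking (SPT)
likelihood is explained by the *emission* model (optics + camera) versus the
*motion* model (transition density)? This package answers that question with
a fully synthetic, end-to-end audit:

1. **Trajectory simulators** for seven diffusion models — Brownian motion
   (BM), drifted BM (DBM), annealed transient time motion (ATTM),
   continuous-time random walks (CTRW), fractional BM via circulant
   embedding (FBM), Lévy walks (LW) and scaled BM (SBM) — on an
   N-frame × K-interpolation acquisition grid.
2. **EMCCD imaging forward model**: pixel- and exposure-integrated Gaussian
   PSF with defocus broadening, uniform background, and high-gain Gamma
   measurement noise `w ~ Gamma(beta*u/2, 2*G/phi)`.
3. **Decomposed log-likelihood**: initial-position term + pixel-wise Gamma
   emission term + BM (or exact DBM/SBM/FBM) motion term, with an
   emission-vs-motion contribution accounting.
4. **MCMC tracker**: Metropolis-within-Gibbs over the full position array
   (rigid, per-point, Brownian-bridge and order-reversal moves; joint
   diffusivity/roughness scaling), scored by 98% credible-interval
   coverage against ground truth.
5. **Experiment pipeline**: per-model contribution audits, one-at-a-time
   parameter sweeps, and the pooled tracking-coverage experiment.

At the reference parameterization (background flux 1e5 /µm²s, emission rate
1e4 /s, NA 1.45, gain 350, 32×32 pixels of 133 nm, 30 ms exposure; N=15
frames, K=10, D=1 µm²/s) the emission side contributes ≈ −1.3·10⁵ to the
log-likelihood and the motion term ≈ +5·10², i.e. the emission model carries
≈ 99.6% of the absolute log-probability.

## Command-line interface

All subcommands accept `--config <yaml>` (missing fields fall back to the
reference defaults), `--seed` and `--out`:

```bash
spt-audit simulate --seed 1 --out traj.csv          # trajectory CSV + JSON sidecar
spt-audit render   --seed 1 --out stack.tiff        # float32 TIFF + JSON sidecar
spt-audit audit    --stack stack.tiff --traj stack.traj.csv --out report.json
spt-audit track    --config cfg.yaml --stack stack.tiff --out chain.npz
spt-audit coverage --chain chain.npz --truth stack.traj.csv --out cov.json
spt-audit experiment --seed 1 --out results/        # audits + sweeps + plots
spt-audit fixtures --seed 0 --out fixtures/         # deterministic test assets
```

An example config showing every field can be produced with
`python -c "import spt_audit.io as io; io.save_config(io.default_config(), 'cfg.yaml')"`.

## Conventions

- Positions are continuous coordinates in micrometres; the ROI's lower-left
  pixel corner defines the edge origin. Pixel indices are 0-based in
  arrays, 1-based in CSV files. Image arrays are indexed `[frame, row(y),
  col(x)]`.
- The K interpolation points sit at midpoints of K equal sub-intervals of
  each frame's exposure; the step bridging consecutive frames spans the
  detector dead time.
- TIFF stacks store float32 ADU (no quantization) with a JSON metadata
  sidecar recording every parameter and seed.
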