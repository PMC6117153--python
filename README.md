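# pvsdwi

Simulation and estimation toolkit for ultra-long-TE, low-b diffusion-weighted
MRI of perivascular and subarachnoid fluid movement.

The package provides:

- **signal_model** — closed-form forward model: spin-echo T2 compartment
  attenuation at the effective echo time, rectangular Stejskal–Tanner
  b-values, and the anisotropic pseudo-diffusion signal
  `S = S0·exp(−b·gᵀDg)`.
- **phantom** — a seeded single-slice digital phantom (128×128, 25×25 mm FOV)
  of the ventral rat brain: subarachnoid CSF around an arterial ring, two
  arterial branches with flanking perivascular tracts, a midline ventricle,
  parenchyma and blood, each with its own T2 and pseudo-diffusion tensor,
  plus Rician noise and physiological scenarios (baseline / pulsation /
  diastole / dobutamine / post-mortem).
- **estimation** — per-direction pseudo-diffusion coefficient D*, log-linear
  least-squares tensor fitting from ≥6 directions + b0, FA/MD/principal
  directions, intensity threshold masking, edge-preserving (median)
  smoothing, and tensor-ellipsoid glyph parameters.
- **gating** — cardiac-gating timing: r-wave delay → diffusion-weighting
  centre and window, pulse-wave arrival, pulsation/diastole classification.
- **stats** — ROI means ± SEM, paired t-tests, percent-change effects.
- **io / cli** — NIfTI-1 volumes with FSL-style `.bval`/`.bvec` sidecars,
  flat-text acquisition configs, and a `pvsdwi` command-line interface.

## Command-line usage

```sh
# render a noisy phantom (CSF b0 SNR 50) with ground truth
pvsdwi simulate --out out/sim --scenario baseline --seed 7 --snr 50

# fit the pseudo-diffusion tensor; writes fa/md/tensor/residual maps + glyph CSV
pvsdwi fit --dwi out/sim/dwi.nii --out out/fit

# per-direction D* maps
pvsdwi dstar --dwi out/sim/dwi.nii --out out/dstar

# cardiac-gating timing plan for a given r-wave delay
pvsdwi gate --rwave-delay 0      # -> centre 36 ms, window 23–49 ms, pulsation
pvsdwi gate --rwave-delay 80     # -> centre 116 ms, window 103–129 ms, diastole

# ROI statistics table
pvsdwi roistats --map fa=out/fit/fa.nii --mask pvs=roi.nii --out stats.csv
```

All lengths are in mm, times in ms, diffusivities in mm²/s and gradient
amplitudes in G/cm at every interface; gradient directions are expressed in
the image frame (x = readout, y = phase, z = slice). Flattened tensor
outputs are ordered (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).

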