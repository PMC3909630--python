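# spectrecon

Scatter- and attenuation-compensated MLEM reconstruction for SPECT.

Photopeak SPECT projections mix attenuated primary photons with Compton-
scattered photons that degrade contrast and quantitation. This package
implements a maximum-likelihood EM reconstruction in which the first-order
scatter model enters the likelihood itself: with an attenuated system
matrix `a^μ_ij` and a scatter kernel `β_ij = ∂SC_i/∂f_j` built from the
Klein–Nishina cross section, the update

    f_j ← (f_j / Σ_i a^μ_ij) Σ_i [ g_i (β_ij + a^μ_ij) / (SC_i + (A^μ f)_i) − β_ij ]

maximises the Poisson likelihood of the contaminated data while the scatter
estimate `SC = β f` is refreshed from the running image every iteration.
When β = SC = 0 it reduces exactly to plain MLEM. The package also provides
the conventional variant (scatter as a fixed additive denominator term),
CT-based attenuation mapping (bilinear HU→μ), digital phantoms (NEMA IQ
and a geometric torso surrogate), a seeded acquisition simulator and the
full image-quality metric set (contrast, MSE, SNR, CNR/CRC/CoV, profiles,
timing). It is aimed at people prototyping or teaching quantitative SPECT
reconstruction who need the whole chain runnable without scanner data.

See `docs/methods.md` for the model, its assumptions and limitations, and
`docs/FORMATS.md` for file formats.

## Worked example

Run a complete seeded NEMA image-quality study — simulate a photopeak
acquisition with attenuation, first-order scatter and Poisson noise, then
reconstruct with every method and score the results:

```python
from spectrecon import ExperimentConfig, run_experiment

cfg = ExperimentConfig(phantom="nema_iq", grid_n=64, n_slices=3, seed=1)
res = run_experiment(cfg, out_dir="run_nema")
for name, r in res.reports.items():
    print(f"{name:12s} Ctr={r.ctr:6.3f}  MSE={r.mse:8.5f}  "
          f"SNR={r.snr:6.2f}  CNR={r.cnr:5.2f}")
```

```
un_cor       Ctr= 2.978  MSE= 0.13794  SNR= 11.24  CNR= 1.20
att_cor      Ctr= 6.213  MSE= 0.03609  SNR= 33.09  CNR= 4.07
conventional Ctr= 6.750  MSE= 0.03012  SNR= 35.11  CNR= 4.37
new1         Ctr= 6.746  MSE= 0.03012  SNR= 35.14  CNR= 4.37
new3         Ctr= 7.583  MSE= 0.02715  SNR= 36.36  CNR= 4.59
```

The true hot-sphere contrast is 8:1, i.e. an ideal contrast of 7.
Uncorrected reconstruction recovers less than half of it; attenuation
correction restores most; adding the scatter model pushes contrast, SNR
and CNR higher still and the error against the reference image lower, with
the 3-slice scatter kernel (`new3`) best. The scatter-gradient updates
cost about 2–5× the conventional update per iteration.

The same pipeline is available from the shell:

```bash
spectrecon simulate --phantom nema_iq --grid 64 --counts 5e5 --seed 42 --out-dir run/
spectrecon reconstruct --sinogram run/sinogram.nii.gz --mu run/mu.nii.gz \
    --method new1 --iterations 50 --out run/f.nii.gz
spectrecon ct2mu --ct ct.nii.gz --energy 140 --out mu.nii.gz
spectrecon run-experiment --seed 1 --out-dir results/
```

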