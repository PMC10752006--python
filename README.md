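# dbsimri

Multi-compartment diffusion MRI analysis of optic nerves: diffusion
basis spectrum imaging (DBSI) and conventional DTI, with a synthetic
phantom cohort generator for traumatic optic neuropathy (TON) studies.

## The problem

Indirect traumatic optic neuropathy — optic nerve injury from force
transmission during head trauma — is routinely missed because visual
testing is insensitive to subclinical lesions, and conventional DTI
conflates coexisting pathologies: axonal injury, demyelination,
inflammatory cellularity and edema all push the single-tensor metrics
in overlapping ways.  DBSI addresses this by decomposing the
diffusion-weighted signal of a coherent fiber bundle into an
anisotropic tensor (the axons) plus a spectrum of isotropic
diffusivities (cells, edema, CSF):

```
S_k / S_0 = f · exp(−|b_k| λ⊥) · exp(−|b_k| (λ∥ − λ⊥) cos²Φ_k)
            + ∫_a^b f(D) · exp(−|b_k| D) dD
```

where `S_k` and `|b_k|` are the signal and b-value of the k-th
diffusion gradient, `Φ_k` the angle between that gradient and the fiber
axis, `f` the fiber signal-intensity fraction (apparent axonal
density), and `λ∥`, `λ⊥` the fiber's axial and radial diffusivities
(axon and myelin integrity).  The isotropic spectrum `f(D)` is
summarised as a **restricted fraction** (ADC ≤ 0.6 µm²/ms, a
cellularity/inflammation marker) and a **non-restricted fraction**
(0.6 < ADC ≤ 3 µm²/ms in vivo, ≤ 2 ex vivo; edema/CSF).  A derived
**axon volume** — nerve volume × fiber fraction — tracks axonal content
without being confounded by nerve swelling.

The inversion is a nested optimisation: a deterministic search over
(λ∥, λ⊥) and the fiber axis wraps a ridge-stabilised non-negative
least-squares solve for the spectrum weights.  See `docs/methods.md`
for the full model, algorithm and phantom description.

This package is aimed at small-animal diffusion-MRI researchers who
want a tested, reproducible reference implementation of the model, the
inversion, and the downstream nerve metrics — plus a phantom generator
to validate pipelines when no raw animal data are available.

## Worked example

Simulate a noise-free voxel with the day-30 TBI optic-nerve composition
(fiber 0.685 at λ∥ = 1.61, λ⊥ = 0.23 µm²/ms; restricted 0.202 at
D = 0.3; non-restricted 0.112 at D = 1.8) on the built-in 25-direction
in vivo scheme (max b = 2,200 s/mm²), and invert it:

```python
from dbsimri import make_scheme, get_preset, simulate_voxel, fit_dbsi, fit_dti

scheme = make_scheme("invivo", seed=0)
preset = get_preset("invivo", "TBI", 30)
signal = simulate_voxel(preset, scheme, snr=None, seed=0)  # noise-free
print(fit_dbsi(signal, scheme).summary())
```

```
DBSI spectrum-inversion fit
---------------------------
  fiber fraction          :  0.6864
  fiber axial diffusivity :  1.6078 um2/ms
  fiber radial diffusivity:  0.2305 um2/ms
  restricted fraction     :  0.1965
  non-restricted fraction :  0.1170
  orientation             : (-0.000,  0.000,  1.000)
  residual norm           :  6.135e-04
  valid                   : True
```

Every compartment fraction is recovered within 0.006 and each
diffusivity within 0.003 µm²/ms of the generator.  The single-tensor
comparison on the same voxel shows the classic confound — the
restricted (cellularity) compartment drags the DTI axial diffusivity
far below the true fiber value:

```python
print(fit_dti(signal, scheme).summary())
```

```
DTI single-tensor fit
---------------------
  axial diffusivity  (AD):  1.2370 um2/ms   # true fiber λ∥ is 1.61
  radial diffusivity (RD):  0.2981 um2/ms
  fractional anisotropy  :  0.7185
  mean diffusivity   (MD):  0.6110 um2/ms
```

Cohort-level work goes through the phantom generator and pipeline:

```sh
dbsimri run -c config.yaml          # simulate → fit → ROI metrics → stats
dbsimri simulate --n-per-group 5 --days 1,3,7,30 -o cohort/
dbsimri fit --dwi dwi.nii --bval a.bval --bvec a.bvec --mask m.nii -o maps/
```

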