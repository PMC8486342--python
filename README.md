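# vshfield

Vector-spherical-harmonic (VSH) multipole modeling and signal-space
separation for quasi-static electromagnetic sensor arrays — MEG
magnetometer arrays and EEG electrode montages in particular.

## The problem and the model

Outside the head, under the quasi-static approximation, both the electric
and the magnetic field of brain activity are curl-free and divergence-free,
so each is the gradient of a harmonic potential.  Expanding that potential
in solid harmonics gives one shared vector basis for both fields:

```
F(r) = c Σ_lm a_lm ν_lm(θ,φ) / r^(l+2)  +  c Σ_lm b_lm r^(l-1) ω_lm(θ,φ)
```

with `c = −1/ε₀` for **E** and `c = −μ₀` for **B**.  The `ν_lm` terms carry
sources *closer* to the expansion origin than the field point (the brain);
the `ω_lm` terms carry *more distant* sources (environmental interference).
The fields differ only through their multipole moments:

* electrostatic: `a_lm = 1/(2l+1) ∫ r'^l Y*_lm ρ(r') dv'`
* magnetostatic: `a_lm = i/(2l+1) √(l/(l+1)) ∫ r'^l X*_lm · J(r') dv'`

where `X_lm` is the tangential VSH.  Because `X₀₀ = 0` there is no magnetic
monopole, and any current element parallel to its position vector is
magnetically silent — the classic insensitivity of MEG to "radial" sources.

Sampling these expansions at a sensor array gives a physics-based signal
basis `d(t) = [S_in S_out] x(t)` with `(L+1)²` components per block
(`(L+1)²−1` for magnetic).  Everything else follows from linear algebra on
that basis: interference suppression (`d_in = S_in x̂_in`, signal space
separation / SSS), low-rank denoising (`S_in S_in⁺ d`), device-independent
standardization (`x̂ = S_in⁺ d`), bad-channel interpolation, and electrode
position calibration by maximizing explained signal variance.

The package also ships the analytic spherical-conductor forward models the
analyses rest on (the Sarvas closed-form MEG field and an M-shell
concentric-sphere EEG potential series) and a synthetic-data module so every
result is reproducible without external recordings.

## Worked example: suppressing interference on a magnetometer array

```python
import numpy as np
import vshfield as vf

meg = vf.generate_array(vf.ArrayRecipe("magnetometer", count=150, seed=0))
scene = vf.SceneRecipe(
    interior=[(vf.CurrentDipole([0.0, 0.01, 0.045], [1e-8, 0, 0]),
               vf.Waveform("sine", freq=10.0))],            # 10 nA·m, 10 Hz
    exterior=[(vf.MagneticDipole([0.5, 1.2, 2.2], [4e-6, -8e-6, 6.4e-6]),
               vf.Waveform("noise", band=(1.0, 60.0)))],    # room-scale noise
    n_samples=256, sfreq=500.0, seed=2)
mixed = vf.simulate_recording(scene, meg)
clean = vf.simulate_recording(vf.SceneRecipe(interior=scene.interior,
                                             n_samples=256, sfreq=500.0,
                                             seed=2), meg)

basis = vf.build_basis(meg, L_in=8, L_out=3)
report = vf.subspace_diagnostics(basis)
print(f"basis: {basis.matrix.shape[1]} components "
      f"({basis.n_in} interior), condition number {report.condition_number:.1f}")

suppressed = vf.suppress_interference(basis, mixed)
before = np.linalg.norm(mixed.values - clean.values) / np.linalg.norm(clean.values)
after = np.linalg.norm(suppressed.values - clean.values) / np.linalg.norm(clean.values)
print(f"interference before suppression: {100*before:.1f}% of the brain signal")
print(f"residual after suppression:      {100*after:.2f}%")

moments = vf.decompose(basis, mixed).interior_moments()
print(f"recovered moment time courses: {moments.a.shape}")
```

prints

```
basis: 95 components (80 interior), condition number 217.3
interference before suppression: 323.5% of the brain signal
residual after suppression:      0.35%
recovered moment time courses: (9, 17, 256)
```

The 150-channel recording contains an interference field three times
stronger than the brain signal; projecting onto the 80 interior + 15
exterior components and reconstructing from the interior part alone removes
it to a third of a percent.  The recovered `a_lm(t)` array (degrees 0–8,
orders −8…8, 256 samples) is the device-independent representation of the
recording.

The same machinery exposes the EEG-specific results: an order-4 potential
basis (25 components) captures ≥ 98 % of a 60-electrode forward model for
superficial sources in the 4-shell spherical head (see
`vshfield dimensionality`), the joint EEG `[S_in S_out]` basis is
ill-conditioned (interior and exterior columns are nearly parallel for
scalar sampling at a single radius, so `suppress_interference` refuses and
recommends `reconstruct_lowrank`), 21 of 60 electrodes suffice to
interpolate an order-2 field exactly, and a 1 cm radial electrode
digitization error is localized to sub-millimeter precision by
`calibrate_positions`.

A thin CLI wraps the same functions:

```sh
vshfield simulate --array meg.csv --scene scene.json --out rec
vshfield suppress --array meg.csv --data rec.data.csv --out clean.csv
vshfield dimensionality --array eeg.csv --l-max 6
vshfield interpolate --array eeg.csv --data d.csv --good EEG000,EEG002 --order 2 --out full.csv
vshfield calibrate --array eeg.csv --data d.csv --adjust EEG007 --order 4
```

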