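# memepr

Spin-label EPR and MD post-processing for model photoreceptor membranes.

Retinal photoreceptor outer segments contain three membrane populations
with very different lipid chemistry: the plasma membrane (PM; PC:PE 5:1,
40 mol% cholesterol, little PUFA), young disc membranes (YDM; PC:PE 1:1,
30 mol% cholesterol, 35 mol% docosahexaenoyl chains) and old disc
membranes (ODM; PC:PE 1:1, only 5 mol% cholesterol).  Retinoids released
during the visual cycle — 11-cis retinal, all-trans retinal and retinol,
and the bisretinoid all-trans retinal dimer — partition into these
bilayers and can perturb their polarity, fluidity and chain order.
`memepr` implements the complete desk-scale analysis chain for studying
those perturbations with nitroxide spin-label EPR and MD-trajectory
post-processing, together with synthetic spectrum and trajectory
generators so that every extraction step can be verified against a known
ground truth.

## What it computes

For a phosphatidylcholine spin label (headgroup T-PC or chain-carbon
n-PC, n ∈ {5, 7, 10, 12, 16}) reporting from a known bilayer depth:

* **Order parameter and cone angle** (ordered regime, 5-PC-like spectra):
  S = 0.5407 (T′∥ − T′⊥)/a₀ with a₀ = (T′∥ + 2T′⊥)/3, where 2T′∥ and
  2T′⊥ are the outer/inner extrema separations of the first-derivative
  spectrum; the wobbling semi-cone angle follows from
  S = cos Θc (1 + cos Θc)/2.
* **Rotational correlation times** (fast regime, 16-PC-like spectra):
  τ₂B = 6.51·10⁻¹⁰ · ΔH₀ · [√(h₀/h₋) − √(h₀/h₊)] s and
  τ₂C = 6.51·10⁻¹⁰ · ΔH₀ · [√(h₀/h₋) + √(h₀/h₊) − 2] s from the central
  peak-to-peak linewidth ΔH₀ (gauss) and the three line amplitudes; the
  index |τ₂C − τ₂B|/τ₂C measures motional anisotropy.
* **Polarity profiles** (rigid limit, frozen samples): 2Azz, the
  outermost-extrema separation, grows with local polarity/hydration and
  maps to an approximate dielectric constant through a solvent
  calibration.
* **Depth profiles and statistics**: observables grouped by label depth,
  control vs retinoid conditions compared per depth with Welch's t-test
  and the `*` (p < 0.05) / `**` (p < 0.02) convention.
* **MD post-processing**: per-carbon molecular order parameters
  Smol = ½(3⟨cos²θ⟩ − 1) from (Cₙ₋₁, Cₙ₊₁) segmental vectors with
  7-block standard errors, and geometric hydrogen-bond counts
  (distance + angle criteria) with a membrane-residency filter.

## Worked example

Simulate a fast-motion chain-end spectrum with a prescribed 0.2 ns
correlation time and recover it through the measurement chain:

```
$ memepr simulate fast --tau-ns 0.2 --seed 3 --out fast.txt
wrote fast.txt (2048 points)
$ memepr extract --in fast.txt --regime fast --smoothing 0.5
{
  "anisotropy_pct": 0.40969899995555975,
  "delta_H0_G": 1.5630546683196371,
  "h_minus": 1.345644481587417,
  "h_plus": 1.937090937944534,
  "h_zero": 1.9355126903550195,
  "tau_2B_ns": 0.20322612229182604,
  "tau_2C_ns": 0.20239690419938017
}
```

The three hyperfine lines have amplitudes h₊ ≈ h₀ > h₋ (the high-field
line broadens as tumbling slows); both correlation times come back within
about 2% of the prescribed 0.2 ns, and their near-equality (anisotropy
≈ 0.4%) reflects the isotropic motion used in the simulation.

The numbered scripts under `analysis/` run the full study chain and write
their tables to `results/`:

```
python analysis/01_membrane_models.py     # Table of the three compositions
python analysis/02_polarity_profiles.py   # 2Azz depth profiles + significance
python analysis/03_order_profiles.py      # S profiles and cone angles
python analysis/04_correlation_times.py   # tau_2B/tau_2C and anisotropy
python analysis/05_md_order.py            # Smol profile + H-bond demo
```

For example, `02_polarity_profiles.py` injects a surface-confined
dehydration (2Azz lowered by ≈1 G from the headgroup to carbon 10) into
the PM model and reports, after re-measuring every simulated spectrum:

```
depths with significant polarity change: T, 5, 7, 10
```

with `**` at the headgroup and carbons 5–7 and no change at carbons
12/16 — the injected depth pattern, recovered end to end.  A complete
seeded run (compose → simulate → extract → profile → MD) with a manifest
is available as `memepr run --out rundir --seed 7`.

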