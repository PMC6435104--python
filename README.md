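# boldopt

Simulation-based BOLD-sensitivity (BS) modelling and automated 2D
gradient-echo EPI protocol optimization from B0 field maps.

Susceptibility gradients near air–tissue interfaces cause through-plane
dephasing, in-plane echo shifts and complete k-space dropout in single-shot
EPI. `boldopt` predicts the relative BS of every voxel from a field map and
an acquisition protocol, and exhaustively searches the adjustable
parameters — z-shim gradient moment, slice tilt / in-plane rotation and
phase-encode (PE) polarity — for the settings that maximize BS voxel-wise
or per region of interest, subject to a hard boundary condition: the BS
loss in well-shimmed tissue must not exceed 15 %.

## What is modelled

For slice-frame gradient components `(G_RO, G_PE, G_SL)` in µT/m:

* **Echo shift** — `q = 1 ∓ (γ/2π)·Δt_eff·FoV_P·G_PE` (− for positive PE
  polarity); local TE = TE₀/q, initial intensity scales with 1/q.
* **Through-plane dephasing** — Gaussian slice profile:
  `Ψ = γ·Δz/(4·ln2)·(G_SL·TE + M_shim)`, attenuation `exp(−Ψ²)`.
* **Dropout** — BS = 0 when the shifted echo leaves the acquisition window
  `TE₀ ± TA/2` (or `q ≤ 0`), or when `|γ·TE·G_RO| > π/Δx`.
* **Relative BS** — `(1/q²)·exp(−(TE−TE₀)/T₂*)·exp(−Ψ²)`, normalized to 1
  for an unperturbed voxel; gains are reported as the symmetric percentage
  `200·(BS−BS_ref)/(BS+BS_ref)`.

GRAPPA acceleration R is modelled as an effective echo spacing `Δt/R`;
phase oversampling enlarges both the acquired line count and FoV. Partial
Fourier is rejected (the dropout condition assumes symmetric sampling).

The default search grid is z-shim −5…5 mT/m·ms in steps of 0.5, tilt
−45…45° in steps of 5°, and both PE polarities (798 parameter sets; the
15 % constraint prunes the strong shims before the argmax).

Also included:

* field-map estimation from double-echo phase data (with quality-guided
  unwrapping) and spacing-aware numerical differentiation into µT/m
  gradient fields,
* an *experimental* BS estimator for complex EPI data (local TE from the
  phase difference of adjacent PE voxels, BS = TE·I) plus
  simulated-vs-experimental gain difference statistics,
* a synthetic head phantom (superposed sphere-dipole air cavities, ±100
  µT/m-scale gradients, labelled ROIs, seeded cohort generation) and a
  per-column EPI forward simulator, so the whole pipeline is testable
  without scanner data.

## Command line

All volumes are NIfTI (field maps in Hz); tables are TSV; units at the CLI
are ms / mm / mT/m·ms / degrees.

```sh
# deterministic synthetic dataset (field maps, mask, ROIs, cohort)
boldopt make-fixtures --out fixtures --seed 0 --n-subjects 6

# relative-BS map for one parameter set
boldopt simulate fixtures/fieldmap_hz.nii --mask fixtures/brain_mask.nii \
    --protocol standard --zshim 1.0 --tilt -15 --polarity negative --out sim/

# grid-search optimization (voxel-wise maps + ROI tables + gain surfaces,
# per-subject histograms when several field maps are given)
boldopt optimize fixtures/subject*_fieldmap_hz.nii \
    --mask fixtures/brain_mask.nii --rois fixtures/rois.nii \
    --roi-names fixtures/roi_names.yaml --out opt/

# compare simulated against experimentally measured BS gain
boldopt validate --magnitude mag.nii --phase pha.nii \
    --magnitude-ref mag0.nii --phase-ref pha0.nii \
    --fieldmap fieldmap_hz.nii --mask brain.nii \
    --polarity negative --out val/
```

Protocol presets: `standard` (3 mm, 64×64, TE 30 ms, Δt 0.5 ms),
`highres` (2 mm, 96×96, Δt 0.78 ms), `grappa2` (highres with GRAPPA 2),
`invivo` (standard + phase oversampling, 74 acquired lines) and
`comparison` (Δt 0.33 ms, 2 mm slices). Custom protocols and grids are
plain YAML files (`--protocol-config`, `--grid-config`).

Conventions worth knowing: the scanner frame is RAS; transverse and
sagittal slices use an anterior→posterior PE axis and coronal uses
feet→head; a positive tilt tips the anterior edge of a transverse slice
towards the feet. The sagittal/coronal rotation senses are package
conventions encoded in `boldopt.geometry` and fixed by unit tests.

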