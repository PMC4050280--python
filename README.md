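# memtomo

Subtomogram averaging and model fitting for membrane-anchored fusogens
in cryo-electron tomography.

Cell–cell fusion proteins sit on membranes at low copy number and modest
contrast; determining whether such a protein is monomeric or oligomeric,
and whether it stands upright or lies flat, requires averaging many
aligned copies picked from tomograms of protein-decorated vesicles.
`memtomo` implements that computational chain end to end, with a
ground-truthed synthetic-scene generator in place of raw tomograms so
every stage can be validated against known answers:

* **Synthetic scenes** — spherical vesicles carrying an elongated
  membrane-anchored phantom (13 nm long, 6 × 4 nm head) with tilt angles
  drawn from a truncated Gaussian (33° ± 17° from the membrane normal,
  uniform azimuth), hard-core surface packing (≥ 10 nm centre-to-centre),
  a ±60° missing wedge, and additive noise at a stated SNR.
* **Picking** — vesicle sphere fitting, subtraction of the rotationally
  symmetric membrane density, thresholded local-minima search
  (mean − 2 SD), membrane-proximity filtering, non-maximum suppression,
  anchor snapping and membrane-normal orientation initialization.
* **Alignment & averaging** — two-stage deterministic grid-search
  refinement (translation-only scoring stage, then masked, wedge-
  compensated, membrane-anchored orientation refinement), above-mean
  correlation selection, even/odd half-set averaging with Fourier shell
  correlation, FSC-matched low-pass filtering, PCA classification and
  back-plotting.
* **Geometry statistics** — per-particle tilt against the membrane
  normal at the anchor, Rayleigh azimuth-uniformity test,
  nearest-neighbour packing, volume-thresholded isosurface levels and
  principal-axis extents.
* **Model fitting** — density synthesis from atomic models, rigid-body
  grid search, hinge-restricted flexible fitting of a three-domain
  architecture (CCC never below the rigid fit), inter-conformation
  domain-rotation measurement and salt-bridge distances.
* **Abundance** — emPAI (`10^(observed/observable) − 1`) and relative
  abundance per preparation, with the fusogen-vesicle proteomics table
  shipped as a fixture.

## Worked example

```sh
python examples/average_and_measure.py
```

runs the whole chain on a small scene (one 450 Å vesicle, 60 particles)
and prints, among other numbers:

```
picked 70 candidates -> 34 selected after scoring
recovered tilt: 25.3 +/- 21.6 deg from the membrane normal (generator: 33 +/- 17)
azimuth uniformity (Rayleigh p): 0.89 (large p = no preferred tilt direction)
nearest-neighbour spacing: min 8.5 nm, median 15.1 nm
FSC resolution: 27 A (0.143), 45 A (0.5)
thresholded average: length 6.5 nm, head cross-section 5.7 x 4.1 nm
```

All numbers are recovered from picked (not ground-truth) particles. At
this small scale the angular recovery is rough — sixty particles is
below what the reference bootstrap needs — but the Rayleigh p-value
already confirms the tilt has no preferred direction and the head
cross-section of the averaged density, thresholded at the volume of one
monomer (87,000 Å³), matches the 6 × 4 nm phantom. At study scale
(500 particles; `scripts/acceptance.py`) the recovered tilt statistics
land at 30–31° ± 19° against the generator's 33° ± 17°. The other
examples demonstrate picking diagnostics
(`simulate_and_pick.py`), hinge-flexible fitting with known rotations
(`fit_atomic_model.py`) and the emPAI table (`abundance_table.py`).

A thin CLI mirrors the stages:

```sh
memtomo simulate --seed 1 --out scene/
memtomo pick scene/tomogram.mrc --out picked.tsv
memtomo run-all --seed 1 --out run/
memtomo abundance --preparation EFF-1
```

## Layout

```
src/memtomo/        library (core_io, synthetic, picking, averaging,
                    geometry, fitting, abundance, pipeline, cli)
examples/           narrative scripts, one per capability
tests/              pytest suite incl. end-to-end acceptance checks
docs/methods.md     model, parameters, design choices, limitations
scripts/acceptance.py   headline-number reproduction
```
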