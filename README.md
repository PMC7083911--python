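# nanospt

Single-particle tracking, Brownian-motion sizing and photon-budget analysis
for near-infrared (NIR) fluorescent nanosheets, with a synthetic-data
generator providing ground truth for every stage.

Exfoliated silicate nanosheets such as Egyptian Blue (CaCuSi₄O₁₀) retain
their ~910 nm Cu²⁺ luminescence down to nanometre dimensions, which makes
them attractive probes for long-term NIR imaging in cells, embryos and
plants. Characterizing them raises three computational problems that this
package solves as one reusable pipeline:

1. **Photon budget** — a single particle's emission saturates with
   excitation power as *I(P) = I_sat·P/(P + P_sat)*. After normalizing
   detected count rates by the optical-efficiency chain (objective
   collection × optics transmission × detector QE, default
   0.70 × 0.50 × 0.05 = 0.0175), the fitted saturation rate converts into
   the number of independently emitting centres, *N = I_sat·τ/Φ*
   (excited-state lifetime τ ≈ 100 µs, quantum yield Φ ≈ 0.1), and — at an
   areal density of 3.8 Cu²⁺ ions nm⁻² — into the side length
   √(N/3.8) of the equivalent square monolayer sheet.
2. **Size from Brownian motion** — diffraction-limited spots are detected
   and linked into trajectories (blob diameter 11 px, search range 9 px,
   gap memory 300 frames), the time-averaged MSD is fitted as
   *MSD = 4·D·τ* up to a 25 s lag window, and the Stokes–Einstein relation
   *R = k_B·T/(6π·η·D)* gives a sphere-equivalent radius that a spheroid
   anisotropy factor (*A* = 1.49) corrects into a hydrodynamic radius.
   Brightness (maximum blob "mass" along a trajectory) versus hydrodynamic
   diameter is then fitted as a power law in log–log space.
3. **In-vivo microrheology** — for particles tracked inside an embryo,
   the self part of the Van Hove function (the distribution of per-axis
   displacements at a 0.1 s lag) is Gaussian for thermal motion; a Gaussian
   fitted to the small-displacement core (±0.03 µm) exposes heavy tails
   produced by active processes, and displacements can be partitioned by
   the distance of their starting point to the nearest nucleus boundary.

## Worked example

Simulate a Poisson-noised saturation sweep of an emitter with
I_sat = 5×10⁵ photons/s and P_sat = 200 µW, then fit it back (unit
efficiency so detected = emitted):

```bash
nanospt simulate saturation --i-sat 500000 --p-sat 200 --seed 7 --out sweep.csv
nanospt fit-saturation sweep.csv --collection 1.0 --transmission 1.0 --detector-qe 1.0
```

```json
{
  "I_sat_per_s": 500637.6532217473,
  "P_sat_uW": 200.70227388579394,
  "plateau_reached": false,
  "N_centers": 500.6376532217472,
  "monolayer_side_nm": 11.478098747084738,
  "monolayer_side_nm_rounded": 11
}
```

Both parameters are recovered to ~0.3% despite shot noise and the sweep
stopping short of the plateau (max power 2.5×P_sat, so
`plateau_reached` is false). The fitted rate corresponds to ≈501
luminescent centres, i.e. an ≈11 nm square monolayer sheet.

Sizing from Brownian motion (20 particles of true Stokes radius 50 nm in
a glycerol-like solvent, 8 fps, 1000 frames):

```bash
nanospt simulate trajectories --n 20 --radius-nm 50 --viscosity 1.19 --out trajs.csv
nanospt size trajs.csv --viscosity 1.19 --out sizes.csv
head -4 sizes.csv
```

```
particle_id,D_um2_s,R_stokes_nm,R_hydro_nm,max_mass
0,0.0047186533,38.480362,57.335739,1
1,0.0042244978,42.981555,64.042517,1
2,0.0048098559,37.750712,56.248562,1
```

Each row is one trajectory: the fitted diffusion coefficient, the
sphere-equivalent Stokes radius, and the anisotropy-corrected
hydrodynamic radius (1.49× larger). Individual 1000-frame tracks carry
~20–30% size noise; cohort medians recover the truth to within 15%
(see `tests/test_acceptance.py`).

End-to-end scenarios (`glycerol`, `embryo`, `photophysics`) run with
`nanospt run --scenario ... --input key=path --out outdir` and write a
reproducible JSON summary including the seed and the provenance
(default vs user-set) of every parameter.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the two photon-budget endpoint conversions from scratch: for
each reported saturation emission rate it simulates a full power sweep
through the detection-efficiency chain, fits the saturation law, and
converts the fitted emitted rate into a luminescent-centre count,
writing the results as JSON.
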