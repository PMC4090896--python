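# skinslide

Plane-stress finite-element simulation of a weight-bearing bony-prominence
region — a 2 mm skin layer over 15 mm of much softer subcutaneous tissue —
sliding frictionally across a hospital mattress during patient
repositioning.

Moisture at the skin–support interface (sweat, urine) raises the
skin–mattress coefficient of friction (COF), and skin stiffens with age and
diabetes. `skinslide` quantifies how those two factors drive the internal
and interface stresses linked to superficial pressure ulcers: it builds the
region-of-interest mesh, solves the two-phase repositioning maneuver
(130 kPa weight-bearing settle, then 10 cm lateral slide + 1 cm immersion
into the mattress) with penalty node-to-segment Coulomb contact and an
incremental Newton solver, and reduces each simulation to its end-point
maxima:

- maximal effective (von Mises) stress
  `σ_vm = √(σxx² − σxx·σyy + σyy² + 3τxy²)` in the skin and subcutis along
  the midline under the prominence apex,
- maximal interface shear traction `|τ| ≤ μ·p` (Coulomb), and
- maximal interface effective stress `√(p² + 3τ²)` from the contact
  pressure p and shear τ.

The headline experiment is a 12-run full cross of COF ∈ {0.2, 0.4, 0.6,
0.8} (dry → wet interface) × skin modulus ∈ {15.2, 50, 100} kPa (young →
aged/diabetic skin), plus a mesh-convergence study and a dry-vs-wet
factorial reduction. The audience is tissue-biomechanics and pressure-ulcer
researchers who want an open, scriptable re-implementation of this class of
contact model.

## Worked example

```python
import skinslide as ss

# one repositioning simulation: wet interface, aged skin
record, arts = ss.run_simulation(ss.RunConfig(mu=0.8, E_skin=100.0))
for key, val in record.as_dict().items():
    print(key, val)
```

prints (kPa, at the end of the maneuver, t = 10 s):

```
mu 0.8
E_skin 100.0
max_skin_effective 3.129548758870232
max_subcutis_effective 1.7170868795905805
max_interface_shear 1.1180505814091264
max_interface_effective 2.3881570887535046
extracted_at_time 10.0
field_max_skin_effective 7.710134321955147
field_max_subcutis_effective 1.7847267470651176
penalty_normal 250.0
max_penetration 0.0055902529070456
n_elements 3350
```

`max_skin_effective` is the largest von Mises stress among the midline skin
elements (the skin is loaded hardest near the contact, so the whole-field
maximum `field_max_skin_effective` is higher); `max_interface_shear` is the
largest frictional traction on the skin–mattress contact, bounded by
μ × pressure at every node. Compare the dry / compliant-skin end of the
design (`mu=0.2, E_skin=15.2`): skin maximum 1.07 kPa and interface shear
0.20 kPa — a wet interface under stiff skin multiplies interface shear
several-fold, which is the study's central point.

The same pipeline is scriptable from the shell:

```bash
skinslide run --mu 0.8 --e-skin 100 --out out/          # one simulation
skinslide sweep --out out/                              # the 12-run table
skinslide converge --levels 3 --out out/                # mesh convergence
skinslide report --results out/results.csv --out out/   # dry-vs-wet effects
skinslide verify                                        # quick self-checks
```

`sweep` writes `results.csv` (one row of maxima per simulation) plus
per-run midline and interface profiles as CSV.

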