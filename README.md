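# ndiskit

Analysis toolkit for **neutron diffraction with isotopic substitution (NDIS)**
of aqueous solutions, aimed at validating molecular-dynamics force fields for
cation–π interactions (e.g. tetramethylammonium binding to pyridine or
phenol). It covers the simulation-and-analysis side of an NDIS study:

- **Difference-function prefactors** from solution composition. For a
  substituted hydrogen class (e.g. the 12 non-exchangeable TMA hydrogens),
  the first-order difference is a weighted sum of Faber–Ziman partial
  structure factors, ΔS(Q) = Σ_X A_X·(S_subX(Q) − 1), with
  A_X = 2·c_sub·c_X·(b_D − b_H)·b_X (self term c_sub²·(b_D² − b_H²)),
  where c are atomic fractions and b coherent scattering lengths; results in
  mbarn. Exchangeable (water) hydrogens take the solvent's isotope, so the
  D₂O- and H₂O-solvent weight sets differ, and their difference — the
  second-order difference ΔΔS(Q) = w₂·(S_subHW(Q) − 1) with
  w₂ = 2·c_sub·c_HW·(b_D − b_H)² — isolates the substituted-H/water-H
  correlation.
- **Partial g(r) and S(Q) from labelled trajectories** (orthorhombic
  periodic boxes; GRO/PDB/XYZ via MDAnalysis): minimum-image histogram RDFs
  with intramolecular exclusion, and the Fourier–Bessel transform pair
  between g(r) and the Faber–Ziman S(Q), with optional Lorch taper.
- **Difference assembly and consistency checks**: build ΔS and ΔΔS from
  partials and weights, extract S_HW from ΔΔS, and test the flatness of a
  second-order difference (the standard check that inelasticity backgrounds
  cancelled between isotopically substituted samples).
- **Gaussian-process comparison to experiment**: a squared-exponential +
  white-noise GP (scikit-learn) fitted to a noisy experimental curve
  estimates the noise floor σ_noise and provides a mean/band against which
  model curves are scored, window-by-window in Q.
- **Aligned 3D density maps**: per-frame least-squares (Kabsch)
  superposition of an aromatic ring onto a canonical frame, bulk-normalised
  voxel maps of a target atom class (OpenDX and Gaussian-cube output), and a
  geometry report that separates **face-on** cation–π binding (density on
  the ring normal) from the **"headphone"** motif (density flanking the ring
  heteroatom in-plane).
- **Synthetic data with planted ground truth** for every stage: ideal-gas
  and lattice configurations, analytic g(r) profiles with known transforms,
  a rigid-molecule solution generator with a planted binding geometry, and
  noisy "experiment" curves with known white-noise level.

## Worked example

The bundled composition — mole ratios 55.508 water : 2 TMA : 2 Cl :
2 pyridine, i.e. a 2-molal TMACl + 2-molal pyridine aqueous solution —
with the packaged coherent scattering lengths:

```sh
$ ndiskit weights
dS_D2O(Q) = 73.4*S[H_TMA,H_W](Q) +31.9*S[H_TMA,O](Q) +11.9*S[H_TMA,C](Q) +3.7*S[H_TMA,N](Q) -3.7*S[H_TMA,H_Py](Q) +1.9*S[H_TMA,Cl](Q) +3.5*S[H_TMA,H_TMA](Q) - 122.6
dS_H2O(Q) = -41.1*S[H_TMA,H_W](Q) +31.9*S[H_TMA,O](Q) +11.9*S[H_TMA,C](Q) +3.7*S[H_TMA,N](Q) -3.7*S[H_TMA,H_Py](Q) +1.9*S[H_TMA,Cl](Q) +3.5*S[H_TMA,H_TMA](Q) - 8.0
ddS(Q) = dS_D2O(Q) - dS_H2O(Q) = 114.6*(S[H_TMA,H_W](Q) - 1)
```

Reading: in the D₂O-solvent sample the TMA-hydrogen/water-hydrogen
correlation enters the measured difference with weight 73.4 mbarn; in the
H₂O sample with −41.1 mbarn (the sign flip follows the negative coherent
scattering length of ¹H). Every other correlation carries the same weight
in both samples, so subtracting the two leaves a single partial structure
factor scaled by 114.6 mbarn — which is why a *flat* measured ΔΔS(Q)
certifies that the four solutions were chemically identical and the
inelasticity background cancelled.

An end-to-end synthetic run (planted face-on binding at 4 Å, RDFs for all
seven pairs, transforms, both differences, GP fit, density map, checksummed
manifest):

```sh
$ ndiskit report --seed 5 --outdir out/
wrote out/manifest.json (26 artifacts)
```

The same from Python:

```python
from ndiskit import (tma_pyridine_composition, difference_weights,
                     second_order_weight, synth, accumulate, geometry_report)

comp = tma_pyridine_composition("D2O")
w_d = difference_weights(comp)
w_h = difference_weights(comp.with_solvent("H2O"))
print(second_order_weight(w_d, w_h))   # 114.5520142562867 mbarn

frames, truth = synth.planted_complex(n_frames=1600, n_water=20, seed=13)
grid = accumulate(frames, ["N_ring", "C_ring"], "C_TMA")
print(geometry_report(grid, level=2.3))
# 195 voxels above 2.3x bulk; peak 100.48x at (-0.25, 0.25, 2.75) A;
# axial fraction 0.97 (face-on)
```

The density peak sits on the ring normal (x, y near zero) inside the
methyl-carbon shell of the cation planted at 4 Å, and nearly all
super-level voxels lie in the 30° cone about the normal — the signature of
face-on cation–π binding. The same analysis on the planted "headphone"
geometry gives an axial fraction near zero.

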