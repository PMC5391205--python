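# peldock

Integrative rigid-body modelling of two-domain proteins from sparse
pulsed-EPR distance measurements, with SAXS cross-validation.

Site-directed spin labelling places a nitroxide reporter at an engineered
cysteine; PELDOR/DEER measures the dipolar coupling between two such
labels and thereby the distribution P(r) of their separation (useful range
roughly 15–80 Å). Given a handful of such measurements between two rigid
domains of known structure, the relative orientation of the domains can be
determined by distance-restrained rigid-body docking. `peldock`
implements that full path for structural biologists and EPR
spectroscopists:

- **Rotamer clouds** — discrete-rotamer MTSL-like label ensembles at any
  backbone site, and predicted inter-label distance distributions
  (`attach_rotamers`, `predict_distance_distribution`, `modal_distance`).
- **DEER inversion** — forward simulation of dipolar traces
  V(t) = [1 − λ + λ(KP)(t)]e^(−kt), background correction, and
  non-negative Tikhonov inversion P = argmin‖KP − F‖² + α²‖LP‖², P ≥ 0,
  with L-curve selection of α (`DeerInversion(trace).fit()`).
- **Two independent docking engines** — a 100,000-decoy search with
  top-200 simplex refinement, and 500-start Powell minimization of the
  harmonic restraint energy Σwᵢ(dᵢ − d_exp,ᵢ)², each returning an accepted
  pose ensemble with quaternion-averaged mean pose, internal Cα RMSD
  statistics, degeneracy clustering and a restraint residual table
  (`RigidBodyDocking(...).fit(method=...)`).
- **SAXS cross-checks** — Debye-formula model intensities, Guinier Rg/I(0),
  and error-weighted scale-fitted χ².
- **Synthetic benchmarks** — ground-truth two-domain toy complexes with
  16 labelled site pairs, noisy dipolar traces and idealized scattering
  curves, so the whole pipeline is testable with no downloads
  (`make_two_domain_toy`, `make_restraint_experiment`).

Real inputs are standard formats: PDB coordinates for the rigid domains,
two-column ASCII dipolar traces, JSON restraint lists, three-column SAXS
`.dat` curves.

## Worked example

Dock a synthetic two-domain complex from its own noise-free restraints
and compare the two engines:

```python
import peldock as pk

fixed, mobile, true_pose = pk.make_two_domain_toy(seed=1)
bench = pk.make_restraint_experiment(fixed, mobile, true_pose,
                                     noise_sigma_trace=0.0, seed=1)

model = pk.RigidBodyDocking(fixed, mobile, bench.restraints,
                            bench.clouds_fixed, bench.clouds_mobile)
decoy = model.fit("decoy", seed=1, n_decoys=20000, top_k=50)
minim = model.fit("minimization", seed=1, n_starts=100)

print(decoy.summary())
print(f"cross-method CA RMSD: {decoy.cross_rmsd(minim):.2f} A")
```

prints (abridged):

```
Restraint-driven rigid-body docking
===================================
engine                           decoy
restraints                          16
accepted poses                      11
pose clusters                        1
internal RMSD pairwise            0.95 Å
internal RMSD to mean             0.64 Å
mean |residual|                   0.12 Å

Residuals (restraint vs averaged model):
       pair  d_exp_A  d_model_A  delta_A
  A:46-B:28    25.50      25.50     0.00
  A:46-B:33    27.50      27.50     0.00
   A:28-B:6    27.50      28.00     0.50
  ...
mean|delta|      NaN        NaN     0.12

cross-method CA RMSD: 0.85 A
```

Reading it: 11 of the 50 refined decoys converged to one pose family
whose members agree to within ~1 Å Cα RMSD; the averaged model reproduces
every modal restraint to half an Ångström or better; and the completely
independent multi-start minimization engine lands on the same
architecture to within ~1 Å.

The same analysis runs from the shell:

```sh
peldock simulate --out-dir bench --seed 1 --noise-sigma 0.0
peldock invert bench/traces/*.dat --out-dir inverted
peldock dock --fixed bench/fixed.pdb --mobile bench/mobile.pdb \
             --restraints bench/restraints.json --out-dir docked
peldock saxs --model docked/decoy/averaged_mobile.pdb \
             --data bench/saxs.dat --out saxs_report.json
```

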