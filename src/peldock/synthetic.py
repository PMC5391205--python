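"""Ground-truth two-domain benchmarks: toy helical-bundle domains at a known
relative pose, labelled site pairs, noisy dipolar traces and an idealized
scattering curve of the true complex.

The toy domains are parametric three-helix bundles built from ideal
alpha-helical backbone geometry (phi = -57, psi = -47 degrees), so every
labelling site carries the backbone N/CA/C atoms the rotamer builder needs.
The mobile domain lives in its own reference frame (centred at the origin);
`true_pose` maps it into the complex. Default experiment conditions —
16 site pairs, 3 microsecond traces at 16 ns steps, modulation depth 0.35,
background decay 0.08 per microsecond, noise sigma 0.01 — emulate a
typical Q-band PELDOR data set on a two-domain protein.

Every benchmark regenerates bitwise from its (manifest, seed).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .deer import BackgroundModel, DipolarTrace, simulate_trace
from .docking import Restraint, restraints_from_json, restraints_to_json
from .geometry import RigidTransform, place_atom, random_rotation
from .labelling import (DistanceDistribution, LabelSite, attach_rotamers,
                        default_r_grid, modal_distance,
                        predict_distance_distribution)
from .saxs import ScatteringCurve, debye_intensity
from .structures import RigidDomain, clash_count, read_pdb, write_pdb

__all__ = [
    "SyntheticBenchmark",
    "make_two_domain_toy",
    "make_restraint_experiment",
    "degrade_restraints",
]

# ideal backbone internal coordinates (bond A, angle deg)
_BB = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
       "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.5}
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

DEFAULT_TRACE = {"t_max_us": 3.0, "dt_us": 0.016,
                 "mod_depth": 0.35, "bg_k_per_us": 0.08, "noise_sigma": 0.01}


def _ideal_helix(n_res: int) -> list[tuple[str, np.ndarray]]:
    """Backbone atoms (N, CA, C, O per residue) of an ideal alpha helix."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["N_CA"], 0.0, 0.0])
    c = place_atom(np.array([-1.0, 1.0, 0.0]), n, ca,
                   _BB["CA_C"], _BB["N_CA_C"], _PHI)
    atoms = [("N", n), ("CA", ca), ("C", c)]
    prev_n, prev_ca, prev_c = n, ca, c
    for _ in range(n_res - 1):
        nn = place_atom(prev_n, prev_ca, prev_c, _BB["C_N"], _BB["CA_C_N"], _PSI)
        nca = place_atom(prev_ca, prev_c, nn, _BB["N_CA"], _BB["C_N_CA"], _OMEGA)
        nc = place_atom(prev_c, nn, nca, _BB["CA_C"], _BB["N_CA_C"], _PHI)
        atoms.extend([("N", nn), ("CA", nca), ("C", nc)])
        prev_n, prev_ca, prev_c = nn, nca, nc
    # carbonyl oxygens, anti to the next N
    full = []
    for i in range(n_res):
        nn, ca_i, c_i = (atoms[3 * i + j][1] for j in range(3))
        full.extend([("N", nn), ("CA", ca_i), ("C", c_i)])
        o = place_atom(nn, ca_i, c_i, _BB["C_O"], _BB["CA_C_O"], _PSI + 180.0)
        full.append(("O", o))
    return full


def _bundle_domain(n_res: int, chain: str, label: str,
                   helix_sep: float = 11.0) -> RigidDomain:
    """Three antiparallel ideal helices on a triangle, numbered 1..n_res."""
    per = n_res // 3
    sizes = [per, per, n_res - 2 * per]
    offsets = helix_sep * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    rows = []
    resnum = 1
    for h, size in enumerate(sizes):
        atoms = _ideal_helix(size)
        xyz = np.array([a[1] for a in atoms])
        # align the helix axis (first principal component) with z
        xyz -= xyz.mean(axis=0)
        _, _, vt = np.linalg.svd(xyz, full_matrices=False)
        axis = vt[0]
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        s, cth = np.linalg.norm(v), float(axis @ z)
        if s > 1e-9:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            Rz = np.eye(3) + vx + vx @ vx * ((1 - cth) / s ** 2)
            xyz = xyz @ Rz.T
        if h == 1:  # antiparallel middle helix
            xyz = xyz @ np.diag([1.0, -1.0, -1.0]).T
        xyz[:, 0] += offsets[h, 0]
        xyz[:, 1] += offsets[h, 1]
        names = [a[0] for a in atoms]
        for i in range(size):
            for j, name in enumerate(names[4 * i:4 * i + 4]):
                rows.append((chain, resnum, "ALA", name,
                             "N" if name == "N" else ("O" if name == "O" else "C"),
                             xyz[4 * i + j]))
            resnum += 1
    dom = RigidDomain.from_atoms(rows, label=label)
    # centre on the origin so the domain frame is its own centroid frame
    return RigidDomain.from_atoms(
        [(dom.chain[i], int(dom.resnum[i]), dom.resname[i], dom.atom_name[i],
          dom.element[i], dom.coords[i] - dom.centroid())
         for i in range(dom.n_atoms)], label=label)


def make_two_domain_toy(n_res_fixed: int = 48, n_res_mobile: int = 48,
                        seed: int = 0, gap: float = 6.0,
                        max_attempts: int = 1000
                        ) -> tuple[RigidDomain, RigidDomain, RigidTransform]:
    """Build a fixed and a mobile helical-bundle domain at a known pose.

    The fixed domain (chain A) sits at the origin of the laboratory frame;
    the mobile domain (chain B) is returned in its own centred frame
    together with the proper rigid `true_pose` placing it next to the fixed
    body, clash-free (heavy-atom 3 A) with at least `gap` Angstrom of
    added separation along the placement direction.
    """
    if n_res_fixed < 30 or n_res_mobile < 30:
        raise ValueError("each domain needs >= 30 residues")
    rng = np.random.default_rng(seed)
    fixed = _bundle_domain(n_res_fixed, "A", "fixed")
    mobile = _bundle_domain(n_res_mobile, "B", "mobile")
    heavy_f = fixed.heavy_coords()
    heavy_m = mobile.heavy_coords()
    for _ in range(max_attempts):
        R = random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rotated = heavy_m @ R.T
        # step the mobile centroid outward until the contact clears, then add gap
        for s in np.arange(10.0, 120.0, 1.0):
            if clash_count(heavy_f, rotated + s * direction, 3.0) == 0:
                t = (s + gap) * direction
                pose = RigidTransform(R, t)
                if clash_count(heavy_f, rotated + t, 3.0) == 0:
                    return fixed, mobile, pose
                break
    raise RuntimeError(f"no clash-free placement found in {max_attempts} attempts")


def _exposed_sites(domain: RigidDomain, k: int) -> list[LabelSite]:
    """Spread-out surface sites: greedy farthest-point picks among the CAs
    most distant from the domain centroid."""
    keys = domain.ca_keys()
    ca = domain.ca_coords()
    centre = domain.centroid()
    radial = np.linalg.norm(ca - centre, axis=1)
    # exclude chain termini and keep the outer half as candidates
    order = np.argsort(radial)[::-1]
    cands = [i for i in order[:max(len(order) // 2, k)]
             if 2 <= i < len(keys) - 2]
    chosen = [cands[0]]
    while len(chosen) < k and len(chosen) < len(cands):
        d = cdist(ca[cands], ca[chosen]).min(axis=1)
        chosen.append(cands[int(np.argmax(d))])
    return [LabelSite(keys[i][0], keys[i][1]) for i in chosen]


@dataclass
class SyntheticBenchmark:
    """A fully specified ground-truth experiment: domains, pose, restraints,
    clouds, true distributions, traces and an idealized scattering curve."""

    fixed: RigidDomain
    mobile: RigidDomain
    true_pose: RigidTransform
    pairs: list
    clouds_fixed: dict
    clouds_mobile: dict
    restraints: list
    true_distributions: list
    traces: list
    scattering: ScatteringCurve
    seed: int
    manifest: dict = field(default_factory=dict)

    def true_complex_ca(self) -> np.ndarray:
        return np.vstack([self.fixed.ca_coords(),
                          self.true_pose.apply(self.mobile.ca_coords())])

    def save(self, out_dir) -> None:
        os.makedirs(os.path.join(out_dir, "traces"), exist_ok=True)
        write_pdb(self.fixed, os.path.join(out_dir, "fixed.pdb"))
        write_pdb(self.mobile, os.path.join(out_dir, "mobile.pdb"))
        self.true_pose.to_json(os.path.join(out_dir, "true_pose.json"))
        restraints_to_json(self.restraints, os.path.join(out_dir, "restraints.json"))
        for i, tr in enumerate(self.traces):
            tr.to_file(os.path.join(out_dir, "traces", f"pair_{i:02d}.dat"))
        self.scattering.to_file(os.path.join(out_dir, "saxs.dat"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1)

    @classmethod
    def load(cls, out_dir) -> "SyntheticBenchmark":
        with open(os.path.join(out_dir, "manifest.json")) as fh:
            manifest = json.load(fh)
        fixed = read_pdb(os.path.join(out_dir, "fixed.pdb"))
        mobile = read_pdb(os.path.join(out_dir, "mobile.pdb"))
        pose = RigidTransform.from_json(os.path.join(out_dir, "true_pose.json"))
        restraints = restraints_from_json(os.path.join(out_dir, "restraints.json"))
        pairs = [(r.site_fixed, r.site_mobile) for r in restraints]
        cseed = manifest["cloud_seed"]
        ncf = manifest["n_conformers"]
        clouds_fixed = {(s.chain, s.resnum): attach_rotamers(fixed, s, ncf, cseed)
                        for s, _ in pairs}
        clouds_mobile = {(s.chain, s.resnum): attach_rotamers(mobile, s, ncf, cseed)
                         for _, s in pairs}
        dists = []
        for sf, sm in pairs:
            cf = clouds_fixed[(sf.chain, sf.resnum)]
            cm = clouds_mobile[(sm.chain, sm.resnum)].transformed(pose)
            dists.append(predict_distance_distribution(cf, cm))
        traces = [DipolarTrace.from_file(os.path.join(out_dir, "traces", f))
                  for f in sorted(os.listdir(os.path.join(out_dir, "traces")))]
        curve = ScatteringCurve.from_file(os.path.join(out_dir, "saxs.dat"))
        return cls(fixed, mobile, pose, pairs, clouds_fixed, clouds_mobile,
                   restraints, dists, traces, curve,
                   seed=manifest["seed"], manifest=manifest)


def make_restraint_experiment(fixed: RigidDomain, mobile: RigidDomain,
                              true_pose: RigidTransform,
                              n_pairs: int = 16,
                              noise_sigma_trace: float = DEFAULT_TRACE["noise_sigma"],
                              distance_jitter: float = 0.0,
                              mod_depth: float = DEFAULT_TRACE["mod_depth"],
                              bg_k: float = DEFAULT_TRACE["bg_k_per_us"],
                              t_max: float = DEFAULT_TRACE["t_max_us"],
                              dt: float = DEFAULT_TRACE["dt_us"],
                              n_conformers: int = 64,
                              seed: int = 0) -> SyntheticBenchmark:
    """Assemble a full synthetic PELDOR experiment on a two-domain complex.

    Labels are attached at spread-out surface sites on both domains (a
    buried site is substituted by the next candidate, recorded in the
    manifest); for each of `n_pairs` site pairs the ground-truth distance
    distribution at `true_pose` is computed, its mode (optionally jittered
    by Gaussian noise of sd `distance_jitter`) becomes the restraint d_exp
    with sigma the distribution half-width, and a dipolar trace is
    simulated with the stated background and noise.
    """
    rng = np.random.default_rng(seed)
    cloud_seed = int(rng.integers(0, 2 ** 31 - 1))
    n_sites = max(int(np.ceil(np.sqrt(n_pairs))) + 1, 4)
    bg = BackgroundModel(k=bg_k, mod_depth=mod_depth)
    t_grid = np.arange(0.0, t_max + dt / 2, dt)
    r_grid = default_r_grid()
    substitutions = []

    while True:
        sites_f = _exposed_sites(fixed, n_sites)
        sites_m = _exposed_sites(mobile, n_sites)

        def grow(domain, sites):
            clouds = {}
            for s in sites:
                site = s
                for shift in range(0, 5):
                    try:
                        cand = LabelSite(s.chain, s.resnum + shift)
                        clouds[(cand.chain, cand.resnum)] = attach_rotamers(
                            domain, cand, n_conformers, cloud_seed)
                        if shift:
                            substitutions.append([str(s), str(cand)])
                        site = cand
                        break
                    except ValueError:
                        continue
                else:
                    raise ValueError(f"no labelable site near {s}")
                yield site, clouds[(site.chain, site.resnum)]

        cf_list = list(grow(fixed, sites_f))
        cm_list = list(grow(mobile, sites_m))
        clouds_fixed = {(s.chain, s.resnum): c for s, c in cf_list}
        clouds_mobile = {(s.chain, s.resnum): c for s, c in cm_list}

        # keep pairs whose full cross-pair distance range sits inside the grid
        valid = []
        for sf, cfc in cf_list:
            for sm, cmc in cm_list:
                posed = cmc.transformed(true_pose)
                d = cdist(cfc.positions, posed.positions)
                if d.min() > r_grid[0] + 1.0 and d.max() < r_grid[-1] - 1.0:
                    dist = predict_distance_distribution(cfc, posed, r_grid)
                    valid.append((sf, sm, dist))
        if len(valid) >= n_pairs or n_sites >= 10:
            break
        n_sites += 1

    if len(valid) < n_pairs:
        raise RuntimeError(f"only {len(valid)} usable site pairs found; "
                           f"needed {n_pairs}")
    # spread the chosen pairs across the accessible distance range
    valid.sort(key=lambda v: modal_distance(v[2]))
    idx = np.unique(np.round(np.linspace(0, len(valid) - 1, n_pairs)).astype(int))
    i = 0
    while len(idx) < n_pairs:  # de-duplicate rounding collisions
        if i not in idx:
            idx = np.sort(np.append(idx, i))
        i += 1
    chosen = [valid[i] for i in idx[:n_pairs]]

    pairs, restraints, dists, traces = [], [], [], []
    for j, (sf, sm, dist) in enumerate(chosen):
        mode = modal_distance(dist)
        jitter = float(rng.normal(0.0, distance_jitter)) if distance_jitter > 0 else 0.0
        d_exp = float(np.clip(mode + jitter, 10.0, 100.0))
        sigma = max(dist.std(), 1.0)
        restraints.append(Restraint(sf, sm, d_exp, sigma))
        pairs.append((sf, sm))
        dists.append(DistanceDistribution(dist.r_grid, dist.density, "ground-truth"))
        trace_seed = int((seed * 100003 + 7919 * j + 1) % (2 ** 31 - 1))
        traces.append(simulate_trace(dist, t_grid, bg,
                                     noise_sigma=noise_sigma_trace,
                                     seed=trace_seed))

    q = np.linspace(0.0, 0.35, 90)
    complex_ca = np.vstack([fixed.ca_coords(),
                            true_pose.apply(mobile.ca_coords())])
    curve = debye_intensity(complex_ca, q, label="true-complex")

    manifest = {
        "seed": int(seed), "cloud_seed": cloud_seed,
        "n_pairs": int(n_pairs), "n_conformers": int(n_conformers),
        "noise_sigma_trace": noise_sigma_trace,
        "distance_jitter_A": distance_jitter,
        "mod_depth": mod_depth, "bg_k_per_us": bg_k,
        "t_max_us": t_max, "dt_us": dt,
        "site_substitutions": substitutions,
        "pairs": [[str(a), str(b)] for a, b in pairs],
        "true_pose": true_pose.to_dict(),
    }
    return SyntheticBenchmark(fixed, mobile, true_pose, pairs,
                              clouds_fixed, clouds_mobile, restraints,
                              dists, traces, curve, seed=seed,
                              manifest=manifest)


def degrade_restraints(benchmark: SyntheticBenchmark, drop_k: int = 0,
                       broaden_factor: float = 1.0,
                       seed: int = 0) -> list[Restraint]:
    """Randomly drop `drop_k` restraints and broaden the rest by a factor."""
    n = len(benchmark.restraints)
    if drop_k >= n:
        raise ValueError("drop_k must be smaller than the restraint count")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n - drop_k, replace=False))
    return [Restraint(r.site_fixed, r.site_mobile, r.d_exp,
                      r.sigma * broaden_factor, r.weight)
            for r in (benchmark.restraints[i] for i in keep)]
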