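"""MTSL-like spin-label rotamer clouds and inter-label distance distributions.

A nitroxide spin label attached through a flexible five-dihedral linker does
not report the position of the host backbone: it reports a *cloud* of
sterically allowed nitroxide positions. This module grows an idealized
MTSL side chain off the site backbone over a discrete rotamer set, rejects
conformers that clash with the host domain, Boltzmann-weights the survivors
by a soft-sphere contact energy, and predicts the distance distribution
P(r) between two such clouds as the weighted histogram of all cross-pair
reporter distances. The reporter point of each conformer is the midpoint
of the nitroxide N-O bond.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import RigidTransform, place_atom
from .structures import RigidDomain

__all__ = [
    "LabelSite",
    "RotamerCloud",
    "DistanceDistribution",
    "attach_rotamers",
    "predict_distance_distribution",
    "modal_distance",
    "default_r_grid",
]

# default distance grid: the useful PELDOR window, 0.5 A steps
R_MIN, R_MAX, R_STEP = 15.0, 80.0, 0.5

# idealized MTSL linker geometry: (bond A, angle deg) for each placed atom
# CA-CB-SG-SD-CE-C3(ring)-N1(ring)-O1; chi1..chi5 are the free torsions.
_CHAIN_GEOMETRY = [
    ("CB", 1.53, 110.5),   # placed from N, CA, C with a fixed branch torsion
    ("SG", 1.81, 114.0),   # chi1: N-CA-CB-SG
    ("SD", 2.04, 104.0),   # chi2: CA-CB-SG-SD
    ("CE", 1.81, 104.0),   # chi3: CB-SG-SD-CE
    ("C3", 1.50, 114.0),   # chi4: SG-SD-CE-C3
    ("N1", 2.35, 120.0),   # chi5: SD-CE-C3-N1 (to the ring nitroxide N)
    ("O1", 1.27, 120.0),   # ring-fixed: C3-N1-O1 at torsion 180
]

# three discrete states per free torsion (gauche-/gauche+/trans)
_CHI_STATES = (-60.0, 60.0, 180.0)
_N_ROTAMERS = 3 ** 5  # 243

_KT_KJ = 2.479          # kT at 298 K, kJ/mol
_SOFT_R0 = 3.5          # soft-sphere contact onset, A
_SOFT_K = 15.0          # kJ/mol/A^2 repulsion stiffness
_SOFT_CAP = 40.0        # cap per conformer so weights never underflow to exactly 0


@dataclass(frozen=True)
class LabelSite:
    """A cysteine-substituted labelling position, addressed as (chain, residue)."""

    chain: str
    resnum: int

    def __str__(self) -> str:
        return f"{self.chain}:{self.resnum}"


@dataclass(frozen=True)
class RotamerCloud:
    """Weighted nitroxide reporter positions of one labelled site.

    `positions` is (n, 3) in the frame of the host domain; `weights` are
    non-negative and sum to one.
    """

    site: LabelSite
    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, float).reshape(-1, 3)
        w = np.asarray(self.weights, float).reshape(-1)
        if len(pos) < 1:
            raise ValueError("empty rotamer cloud")
        if len(pos) != len(w):
            raise ValueError("positions/weights length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def centroid(self) -> np.ndarray:
        return self.weights @ self.positions

    def radius(self) -> float:
        """Max distance of any conformer from the weighted centroid."""
        return float(np.linalg.norm(self.positions - self.centroid(), axis=1).max())

    def transformed(self, t: RigidTransform) -> "RotamerCloud":
        return replace(self, positions=t.apply(self.positions))


@dataclass(frozen=True)
class DistanceDistribution:
    """P(r) on a strictly increasing grid, normalized to unit trapezoid integral."""

    r_grid: np.ndarray
    density: np.ndarray
    provenance: str = "predicted"  # predicted | inverted | ground-truth

    def __post_init__(self):
        r = np.asarray(self.r_grid, float)
        p = np.asarray(self.density, float)
        if r.ndim != 1 or len(r) < 2 or np.any(np.diff(r) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if p.shape != r.shape:
            raise ValueError("density/grid shape mismatch")
        if np.any(p < -1e-12):
            raise ValueError("density must be non-negative")
        p = np.clip(p, 0.0, None)
        integral = np.trapezoid(p, r)
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(f"density integral {integral} != 1")
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "density", p)

    @classmethod
    def from_unnormalized(cls, r_grid, density, provenance="predicted") -> "DistanceDistribution":
        r = np.asarray(r_grid, float)
        p = np.clip(np.asarray(density, float), 0.0, None)
        z = np.trapezoid(p, r)
        if z <= 0:
            raise ValueError("all-zero density cannot be normalized")
        return cls(r, p / z, provenance)

    def mean(self) -> float:
        return float(np.trapezoid(self.r_grid * self.density, self.r_grid))

    def std(self) -> float:
        m = self.mean()
        var = float(np.trapezoid((self.r_grid - m) ** 2 * self.density, self.r_grid))
        return float(np.sqrt(max(var, 0.0)))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# r_A,P\n")
            for r, p in zip(self.r_grid, self.density):
                fh.write(f"{r:.6g},{p:.8g}\n")

    @classmethod
    def from_csv(cls, path, provenance="predicted") -> "DistanceDistribution":
        data = np.loadtxt(path, delimiter=",", comments="#")
        return cls.from_unnormalized(data[:, 0], data[:, 1], provenance)

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.r_grid, self.density, **kw)
        ax.set_xlabel("r (Å)")
        ax.set_ylabel("P(r)")
        return ax


def default_r_grid() -> np.ndarray:
    return np.arange(R_MIN, R_MAX + R_STEP / 2, R_STEP)


def _build_conformer(n, ca, c, chis):
    """Grow the label side chain off backbone N/CA/C for one torsion state."""
    # CB branches off CA; its torsion relative to N-C-CA fixes tetrahedral geometry
    cb = place_atom(n, c, ca, _CHAIN_GEOMETRY[0][1], _CHAIN_GEOMETRY[0][2], 122.5)
    chain = [n, ca, cb]
    torsions = list(chis) + [180.0]  # final ring-fixed O1 torsion
    for (name, bond, angle), chi in zip(_CHAIN_GEOMETRY[1:], torsions):
        chain.append(place_atom(chain[-3], chain[-2], chain[-1], bond, angle, chi))
    side = np.array(chain[2:])       # CB SG SD CE C3 N1 O1
    reporter = 0.5 * (side[-2] + side[-1])
    return side, reporter


def attach_rotamers(domain: RigidDomain, site: LabelSite,
                    n_conformers: int = 64, seed: int = 0,
                    clash_cutoff: float = 2.5,
                    weight_mode: str = "boltzmann") -> RotamerCloud:
    """Build the rotamer cloud of an MTSL-like label at `site`.

    Conformers are generated by sampling (without replacement, seeded) from
    the 243-member discrete rotamer set (three states per linker dihedral),
    anchored on the site backbone N/CA/C. A conformer is rejected when any
    of its side-chain heavy atoms comes within `clash_cutoff` of a host
    heavy atom outside the site residue. Surviving conformers are weighted
    Boltzmann (T = 298 K) over a capped soft-sphere contact energy, or
    uniformly with ``weight_mode="uniform"``.

    Raises
    ------
    ValueError
        If backbone atoms are missing or no conformer survives the clash
        filter (fully buried site).
    """
    if weight_mode not in ("boltzmann", "uniform"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    try:
        bb_n = domain.atom_coord(site.chain, site.resnum, "N")
        bb_ca = domain.atom_coord(site.chain, site.resnum, "CA")
        bb_c = domain.atom_coord(site.chain, site.resnum, "C")
    except KeyError as e:
        raise ValueError(f"site {site} lacks backbone atoms: {e}") from e

    all_states = list(itertools.product(_CHI_STATES, repeat=5))
    rng = np.random.default_rng(seed)
    k = min(int(n_conformers), _N_ROTAMERS)
    if k < 1:
        raise ValueError("n_conformers must be >= 1")
    idx = rng.choice(_N_ROTAMERS, size=k, replace=False)
    idx.sort()

    host_mask = ~domain.residue_mask(site.chain, site.resnum) & (domain.element != "H")
    host = domain.coords[host_mask]
    tree = cKDTree(host) if len(host) else None

    positions, energies = [], []
    for i in idx:
        side, reporter = _build_conformer(bb_n, bb_ca, bb_c, all_states[i])
        if tree is not None:
            dmin, _ = tree.query(side, k=1)
            if np.min(dmin) < clash_cutoff:
                continue
            # soft-sphere energy over contacts inside the onset radius
            close = tree.query_ball_point(side, _SOFT_R0)
            e = 0.0
            for atom_xyz, nbrs in zip(side, close):
                if nbrs:
                    d = np.linalg.norm(host[nbrs] - atom_xyz, axis=1)
                    e += _SOFT_K * np.sum((_SOFT_R0 - d) ** 2)
            energies.append(min(e, _SOFT_CAP))
        else:
            energies.append(0.0)
        positions.append(reporter)

    if not positions:
        raise ValueError(f"no clash-free rotamers at site {site}")
    positions = np.array(positions)
    if weight_mode == "uniform":
        w = np.full(len(positions), 1.0 / len(positions))
    else:
        e = np.asarray(energies)
        w = np.exp(-(e - e.min()) / _KT_KJ)
        w /= w.sum()
    return RotamerCloud(site=site, positions=positions, weights=w)


def cloud_to_pdb(cloud: RotamerCloud, path) -> None:
    """Export a cloud as a multi-model PDB (one reporter pseudo-atom per MODEL)."""
    with open(path, "w") as fh:
        for i, (xyz, w) in enumerate(zip(cloud.positions, cloud.weights), 1):
            fh.write(f"MODEL     {i:4d}\n")
            fh.write(f"ATOM  {1:5d}  NO  MTS {cloud.site.chain}{cloud.site.resnum:4d}    "
                     f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{w:6.2f}  0.00           N\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def predict_distance_distribution(a: RotamerCloud, b: RotamerCloud,
                                  r_grid: np.ndarray | None = None,
                                  smoothing_sigma: float = 1.0) -> DistanceDistribution:
    """P(r) between two clouds: weighted cross-pair histogram, kernel-smoothed.

    Every pair (i in a, j in b) contributes mass w_i * w_j at distance
    ||a_i - b_j||; the histogram on `r_grid` is convolved with a Gaussian of
    width `smoothing_sigma` (0 disables smoothing) and renormalized.
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    if r_grid is None:
        r_grid = default_r_grid()
    r_grid = np.asarray(r_grid, float)
    d = cdist(a.positions, b.positions).ravel()
    w = np.outer(a.weights, b.weights).ravel()
    dr = r_grid[1] - r_grid[0]
    if d.min() < r_grid[0] - dr / 2 or d.max() > r_grid[-1] + dr / 2:
        raise ValueError(
            f"grid [{r_grid[0]}, {r_grid[-1]}] does not cover observed distances "
            f"[{d.min():.1f}, {d.max():.1f}]")
    edges = np.concatenate([[r_grid[0] - dr / 2], r_grid + dr / 2])
    hist, _ = np.histogram(d, bins=edges, weights=w)
    if smoothing_sigma > 0:
        half = int(np.ceil(4 * smoothing_sigma / dr))
        x = np.arange(-half, half + 1) * dr
        kernel = np.exp(-0.5 * (x / smoothing_sigma) ** 2)
        kernel /= kernel.sum()
        hist = np.convolve(hist, kernel, mode="same")
    return DistanceDistribution.from_unnormalized(r_grid, hist / dr)


def modal_distance(d: DistanceDistribution, interpolate: bool = False) -> float:
    """Most probable distance: r at the global maximum of P(r).

    Ties break toward smaller r. With `interpolate`, a parabola through the
    peak node and its neighbours refines the mode off-grid (used by the
    docking refinement stage, where a continuous objective is needed).
    """
    p = d.density
    if not np.any(p > 0):
        raise ValueError("all-zero density has no mode")
    i = int(np.argmax(p))
    if not interpolate or i == 0 or i == len(p) - 1:
        return float(d.r_grid[i])
    y0, y1, y2 = p[i - 1], p[i], p[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= -1e-300:  # flat top: stay on the grid node
        return float(d.r_grid[i])
    shift = 0.5 * (y0 - y2) / denom
    dr = d.r_grid[1] - d.r_grid[0]
    return float(d.r_grid[i] + np.clip(shift, -0.5, 0.5) * dr)
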