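"""Coarse-grained SAXS cross-validation: Debye intensities, Guinier fits,
scale-fitted chi-square.

Model intensities are computed with the Debye formula over one scattering
point per CA with uniform weight — no hydration shell or excluded-volume
term, so absolute agreement with solvent-corrected experimental fits is
not expected; the role of this module is relative model ranking and
low-q (Rg, I0) consistency checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ScatteringCurve",
    "GuinierResult",
    "ChiSquareReport",
    "debye_intensity",
    "guinier_fit",
    "chi_square",
    "model_pr",
    "radius_of_gyration",
]


@dataclass(frozen=True)
class ScatteringCurve:
    """One-dimensional scattering profile I(q) with point errors."""

    q: np.ndarray          # A^-1, increasing; q = 0 allowed as first point
    intensity: np.ndarray  # > 0
    sigma: np.ndarray      # > 0
    label: str = "curve"

    def __post_init__(self):
        q = np.asarray(self.q, float)
        i = np.asarray(self.intensity, float)
        s = np.asarray(self.sigma, float)
        if not (q.shape == i.shape == s.shape) or q.ndim != 1:
            raise ValueError("q/I/sigma must be equal-length 1-D arrays")
        if np.any(np.diff(q) <= 0) or np.any(q < 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if np.any(i <= 0):
            raise ValueError("intensities must be positive")
        if np.any(s <= 0):
            raise ValueError("errors must be positive")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.label}\n# q_A^-1 I sigma\n")
            for q, i, s in zip(self.q, self.intensity, self.sigma):
                fh.write(f"{q:.6f} {i:.8g} {s:.8g}\n")

    @classmethod
    def from_file(cls, path, label=None) -> "ScatteringCurve":
        data = np.loadtxt(path, comments="#")
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"curve file {path} must have >= 2 columns")
        q, i = data[:, 0], data[:, 1]
        s = data[:, 2] if data.shape[1] > 2 else 0.02 * i
        return cls(q, i, s, label=label or str(path))

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.q, self.intensity, yerr=self.sigma, fmt=".", ms=3, **kw)
        ax.set_yscale("log")
        ax.set_xlabel("q (Å$^{-1}$)")
        ax.set_ylabel("I(q)")
        return ax


@dataclass(frozen=True)
class GuinierResult:
    """Low-q linear fit ln I = ln I0 - q^2 Rg^2 / 3."""

    rg: float
    i0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float

    def __post_init__(self):
        if self.rg <= 0:
            raise ValueError("Rg must be positive")


@dataclass(frozen=True)
class ChiSquareReport:
    """Scale-fitted reduced chi-square between a model and a data curve."""

    chi2: float
    scale: float
    n_points: int

    def __post_init__(self):
        if self.chi2 < 0:
            raise ValueError("chi-square must be >= 0")


def radius_of_gyration(coords: np.ndarray, weights=None) -> float:
    """Mass-weighted Rg of a point set."""
    x = np.asarray(coords, float)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    c = (w[:, None] * x).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((x - c) ** 2, axis=1)).sum() / w.sum()))


def debye_intensity(coords: np.ndarray, q_grid: np.ndarray,
                    weights=None, sigma_frac: float = 0.02,
                    label: str = "model") -> ScatteringCurve:
    """Debye-formula scattering of a weighted point set.

    I(q) = sum_ij f_i f_j sin(q r_ij) / (q r_ij), with the i = j diagonal
    and the q -> 0 limit handled analytically (sinc -> 1), so
    I(0) = (sum f_i)^2 exactly. Error bars are synthetic (`sigma_frac` of
    I) so the curve can be fed to the chi-square machinery.
    """
    x = np.asarray(coords, float).reshape(-1, 3)
    if len(x) < 1:
        raise ValueError("need at least one scattering point")
    q = np.asarray(q_grid, float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    f = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    d = pdist(x)
    fw = (np.outer(f, f) - np.diag(f ** 2))[np.triu_indices(len(x), 1)]
    intensity = np.empty(len(q))
    diag = np.sum(f ** 2)
    for m, qv in enumerate(q):
        if qv == 0:
            intensity[m] = diag + 2 * fw.sum()
            continue
        arg = qv * d
        sinc = np.ones_like(arg)
        nz = arg != 0
        sinc[nz] = np.sin(arg[nz]) / arg[nz]
        intensity[m] = diag + 2 * np.sum(fw * sinc)
    return ScatteringCurve(q, intensity, sigma_frac * np.abs(intensity),
                           label=label)


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3) -> GuinierResult:
    """Guinier analysis: iterated low-q window with max q*Rg <= `qrg_limit`.

    Two-pass: fit from the smallest q over a generous window, estimate Rg,
    shrink the window to q*Rg <= limit, refit once. Needs >= 5 points in
    the final window.
    """
    q, i = curve.q, curve.intensity
    pos = q > 0
    q, i = q[pos], i[pos]
    if np.any(i <= 0):
        raise ValueError("non-positive intensities in Guinier window")

    def fit(mask):
        if mask.sum() < 5:
            raise ValueError("Guinier window collapsed below 5 points")
        slope, intercept = np.polyfit(q[mask] ** 2, np.log(i[mask]), 1)
        if slope >= 0:
            raise ValueError("non-decreasing low-q intensity: no Guinier regime")
        rg = float(np.sqrt(-3 * slope))
        resid = np.log(i[mask]) - (intercept + slope * q[mask] ** 2)
        tot = np.log(i[mask]) - np.log(i[mask]).mean()
        ss_tot = float(np.sum(tot ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return rg, float(np.exp(intercept)), r2

    # pass one: the lowest-q quarter of the curve (at least 5 points)
    n0 = max(5, len(q) // 4)
    rg0, _, _ = fit(np.arange(len(q)) < n0)
    window = q * rg0 <= qrg_limit
    rg, i0, r2 = fit(window)
    qw = q[window]
    return GuinierResult(rg=rg, i0=i0, q_min=float(qw[0]), q_max=float(qw[-1]),
                         n_points=int(window.sum()), r_squared=r2)


def chi_square(model: ScatteringCurve, data: ScatteringCurve) -> ChiSquareReport:
    """Reduced chi-square of a model curve against data with analytic scaling.

    The model is linearly interpolated to the data grid; the scale s
    minimizing sum ((s I_m - I_d)/sigma)^2 is closed-form, and
    chi2 = sum / (N - 1).
    """
    if model.q[-1] < data.q[0] or model.q[0] > data.q[-1]:
        raise ValueError("disjoint q ranges between model and data")
    inside = (data.q >= model.q[0]) & (data.q <= model.q[-1])
    qd = data.q[inside]
    i_d = data.intensity[inside]
    s_d = data.sigma[inside]
    if len(qd) < 2:
        raise ValueError("fewer than 2 overlapping q points")
    i_m = np.interp(qd, model.q, model.intensity)
    w = 1.0 / s_d ** 2
    scale = float(np.sum(w * i_m * i_d) / np.sum(w * i_m ** 2))
    chi2 = float(np.sum(((scale * i_m - i_d) / s_d) ** 2) / (len(qd) - 1))
    return ChiSquareReport(chi2=chi2, scale=scale, n_points=len(qd))


def model_pr(coords: np.ndarray, bin_width: float = 1.0):
    """Normalized pair-distance histogram P(r) of a point set.

    Returns (bin centres, normalized counts, maximum distance).
    """
    x = np.asarray(coords, float).reshape(-1, 3)
    if len(x) < 2:
        raise ValueError("need >= 2 points for a pair-distance histogram")
    d = pdist(x)
    dmax = float(d.max())
    n_bins = max(int(np.ceil(dmax / bin_width)), 1)
    hist, edges = np.histogram(d, bins=n_bins, range=(0, n_bins * bin_width))
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, hist / hist.sum(), dmax


def saxs_report(model_curve: ScatteringCurve, data_curve: ScatteringCurve,
                qrg_limit: float = 1.3) -> dict:
    """Combined chi-square + Guinier JSON-ready report."""
    chi = chi_square(model_curve, data_curve)
    gu = guinier_fit(data_curve, qrg_limit)
    return {"chi2": round(chi.chi2, 4), "scale": round(chi.scale, 6),
            "n_points": chi.n_points, "rg_A": round(gu.rg, 3),
            "i0": round(gu.i0, 6), "guinier_n_points": gu.n_points,
            "guinier_q_range": [round(gu.q_min, 5), round(gu.q_max, 5)],
            "guinier_r_squared": round(gu.r_squared, 5)}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
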