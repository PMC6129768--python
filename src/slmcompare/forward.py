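"""Forward model: 3-shell spherical head, electrode montages, lead fields.

The head is modeled as three nested concentric spherical shells (brain,
skull, scalp) with homogeneous isotropic conductivities.  The potential of a
current dipole inside the innermost shell is the truncated spherical-
harmonic series solution of the Laplace problem with an insulating outer
boundary; per harmonic degree the radial two-coefficient solutions of all
layers are matched at the interfaces by solving a small linear system, so
the same code handles any number of shells (a single shell reproduces the
classical homogeneous-sphere factor (2n+1)/n).

Units: positions in mm, conductivities in S/m, dipole moments in nA·m,
potentials in µV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .source_space import SourceSpace

__all__ = [
    "HeadModel",
    "ElectrodeMontage",
    "LeadField",
    "SeriesConvergenceWarning",
    "load_montage",
    "make_standard_montage",
    "dipole_potential",
    "compute_lead_field",
]


class SeriesConvergenceWarning(UserWarning):
    """The spherical-harmonic series had a non-negligible last term."""


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell conductor.

    radii : shell outer radii in mm, strictly increasing (brain, skull, scalp).
    conductivities : S/m per shell.
    series_order : truncation degree of the harmonic expansion.
    """

    radii: tuple[float, ...] = (83.0, 88.0, 94.0)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)
    series_order: int = 120

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must pair up")
        if any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.series_order < 1:
            raise ValueError("series_order must be >= 1")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


@lru_cache(maxsize=32)
def _layer_transfer(radii: tuple, sigmas: tuple, nmax: int) -> np.ndarray:
    """Per-degree surface value of the multilayer solution for a unit
    singular coefficient (B_1 = 1) of the dipole field in layer 1.

    Radii in meters.  T[n] is the factor replacing the homogeneous
    r^-(n+1)-at-surface evaluation; for one layer T[n] = (2n+1)/n / R^(n+1).
    """
    m = len(radii)
    T = np.zeros(nmax + 1)
    for n in range(1, nmax + 1):
        nu = 2 * m - 1
        A = np.zeros((nu, nu))
        b = np.zeros(nu)

        def ai(k: int) -> int:
            return 0 if k == 1 else 2 * (k - 1) - 1

        def bi(k: int) -> int:
            return 2 * (k - 1)

        row = 0
        for k in range(1, m):
            r = radii[k - 1]
            # potential continuity at interface k
            A[row, ai(k)] += r**n
            if k > 1:
                A[row, bi(k)] += r ** -(n + 1)
            else:
                b[row] -= r ** -(n + 1)  # B_1 = 1 contribution
            A[row, ai(k + 1)] -= r**n
            A[row, bi(k + 1)] -= r ** -(n + 1)
            row += 1
            # radial current continuity
            s1, s2 = sigmas[k - 1], sigmas[k]
            A[row, ai(k)] += s1 * n * r ** (n - 1)
            if k > 1:
                A[row, bi(k)] += -s1 * (n + 1) * r ** -(n + 2)
            else:
                b[row] -= -s1 * (n + 1) * r ** -(n + 2)
            A[row, ai(k + 1)] -= s2 * n * r ** (n - 1)
            A[row, bi(k + 1)] -= -s2 * (n + 1) * r ** -(n + 2)
            row += 1
        # insulating outer boundary
        R = radii[-1]
        A[row, ai(m)] = n * R ** (n - 1)
        if m > 1:
            A[row, bi(m)] = -(n + 1) * R ** -(n + 2)
            sol = np.linalg.solve(A, b)
            T[n] = sol[ai(m)] * R**n + sol[bi(m)] * R ** -(n + 1)
        else:
            b[0] = (n + 1) * R ** -(n + 2)
            sol = np.linalg.solve(A, b)
            T[n] = sol[0] * R**n + R ** -(n + 1)
    return T


@dataclass
class ElectrodeMontage:
    """Named electrode positions projected onto the scalp sphere."""

    names: list[str]
    positions: np.ndarray
    reference: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(self.positions):
            raise ValueError("names and positions must pair up")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")

    def __len__(self) -> int:
        return len(self.names)


def load_montage(path: str | Path, scalp_radius: float = 94.0) -> ElectrodeMontage:
    """Read a .sfp-style montage (``label x y z`` per line, whitespace- or
    tab-separated) and project every position onto the scalp sphere."""
    names: list[str] = []
    raw: list[list[float]] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.replace("\t", " ").split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {lineno}: expected 'label x y z'")
        names.append(parts[0])
        raw.append([float(p) for p in parts[1:4]])
    if not names:
        raise ValueError(f"{path}: montage file has no channels")
    pos = np.asarray(raw)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        zero = [names[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-length position vector for channels {zero}")
    pos = pos / norms[:, None] * scalp_radius
    return ElectrodeMontage(names, pos)


def make_standard_montage(n_channels: int = 128, scalp_radius: float = 94.0) -> ElectrodeMontage:
    """Deterministic extended-10-20-style cap of ``n_channels`` electrodes.

    Electrodes are placed on a Fibonacci spiral restricted to the upper
    portion of the scalp sphere (down to ~30 degrees below the equator,
    roughly where an extended 10-20 high-density cap ends), ordered from
    vertex outward.  Channel names are E001..E***.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    z_min = -0.5  # cos(120 deg): lowest cap latitude
    k = np.arange(n_channels)
    z = 1.0 - (1.0 - z_min) * (k + 0.5) / n_channels
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(1.0 - z**2)
    pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z]) * scalp_radius
    names = [f"E{i + 1:03d}" for i in range(n_channels)]
    return ElectrodeMontage(names, pos)


@dataclass
class LeadField:
    """Gain matrix mapping source dipole moments to electrode potentials.

    matrix : (N_e, 3*N_s) in µV per nA·m; columns grouped as consecutive
    (x, y, z) triples per source vertex.
    """

    matrix: np.ndarray
    electrode_names: list[str]
    source_space: SourceSpace = field(repr=False)
    average_reference: bool = True
    source_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != 3 * self.source_space.n_sources:
            raise ValueError("lead field must have 3 columns per source vertex")

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.source_space.n_sources

    def column_group(self, p: int) -> np.ndarray:
        """Column indices I_p of source point p."""
        return np.arange(3 * p, 3 * p + 3)


# scale: SI gain [V/(A·m)] with meters -> µV/(nA·m)
_UNIT_SCALE = 1e-3


def _gain_vectors(
    head: HeadModel, sources_mm: np.ndarray, electrodes_mm: np.ndarray
) -> tuple[np.ndarray, float]:
    """Vectorized unit-moment gains.

    Returns (E, P, 3) array g such that the potential of moment m (nA·m) at
    source p seen by electrode e is g[e, p] @ m, in µV; plus the worst
    last-term-to-total ratio for convergence checking.
    """
    radii_m = tuple(r * 1e-3 for r in head.radii)
    T = _layer_transfer(radii_m, tuple(head.conductivities), head.series_order)
    src = np.asarray(sources_mm, dtype=float) * 1e-3
    ele = np.asarray(electrodes_mm, dtype=float) * 1e-3
    b = np.linalg.norm(src, axis=1)  # (P,)
    if np.any(b >= radii_m[0]):
        bad = np.flatnonzero(b * 1e3 >= head.brain_radius)
        raise ValueError(f"sources on/outside the brain shell: {bad[:10].tolist()}")
    rb = np.where(b[:, None] > 0, src / np.where(b[:, None] == 0, 1.0, b[:, None]),
                  np.array([0.0, 0.0, 1.0]))
    re = ele / np.linalg.norm(ele, axis=1)[:, None]
    x = np.clip(re @ rb.T, -1.0, 1.0)  # (E, P) cos of angle
    s = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    # tangential unit vector per (e, p): (re - x*rb)/s, zero where collinear
    t = re[:, None, :] - x[..., None] * rb[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(s[..., None] > 1e-12, t / np.where(s[..., None] == 0, 1.0, s[..., None]), 0.0)
    # Legendre recurrences accumulated in-place
    nmax = head.series_order
    P_nm1 = np.ones_like(x)   # P_0
    P_n = x.copy()            # P_1
    P1_nm1 = np.zeros_like(x)
    P1_n = s.copy()           # P_1^1 (positive convention)
    f = b  # radius in m; series term carries b^(n-1)
    Sr = np.zeros_like(x)
    St = np.zeros_like(x)
    last = np.zeros_like(x)
    bn = np.ones_like(b)  # b^(n-1)
    for n in range(1, nmax + 1):
        term_r = T[n] * bn[None, :] * n * P_n
        term_t = T[n] * bn[None, :] * P1_n
        Sr += term_r
        St += term_t
        last = np.abs(term_r) + np.abs(term_t)
        if n < nmax:
            P_np1 = ((2 * n + 1) * x * P_n - n * P_nm1) / (n + 1)
            P1_np1 = ((2 * n + 1) * x * P1_n - (n + 1) * P1_nm1) / n
            P_nm1, P_n = P_n, P_np1
            P1_nm1, P1_n = P1_n, P1_np1
            bn = bn * f
    scale = _UNIT_SCALE / (4 * np.pi * head.conductivities[0])
    gain = scale * (Sr[..., None] * rb[None, :, :] + St[..., None] * t)
    total = np.abs(Sr) + np.abs(St)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, last / total, 0.0)
    return gain, float(ratio.max())


def dipole_potential(
    head: HeadModel, src: np.ndarray, moment: np.ndarray, electrode: np.ndarray
) -> float:
    """Potential (µV) of one dipole (moment in nA·m) at one scalp electrode.

    Warns with :class:`SeriesConvergenceWarning` if the truncated series'
    last term contributes more than 1e-8 of the total.
    """
    src = np.asarray(src, dtype=float)
    if np.linalg.norm(src) >= head.brain_radius:
        raise ValueError("dipole must lie strictly inside the brain shell")
    gain, worst = _gain_vectors(head, src[None, :], np.asarray(electrode, dtype=float)[None, :])
    if worst > 1e-8:
        warnings.warn(
            f"series truncated at order {head.series_order} with last-term "
            f"ratio {worst:.2e}", SeriesConvergenceWarning, stacklevel=2,
        )
    return float(gain[0, 0] @ np.asarray(moment, dtype=float))


def compute_lead_field(
    head: HeadModel,
    montage: ElectrodeMontage,
    space: SourceSpace,
    average_reference: bool = True,
    fit_to_sphere: bool = True,
    fit_fraction: float = 0.95,
) -> LeadField:
    """Assemble the (N_e x 3*N_s) gain matrix for unit x/y/z moments.

    Cortical meshes are affinely shrunk so the outermost vertex sits at
    ``fit_fraction`` of the brain radius (surface source models and spherical
    conductors otherwise disagree about scale); set ``fit_to_sphere=False``
    to require the mesh to fit as-is, in which case offending vertices raise.
    """
    pos = space.vertices
    rmax = np.linalg.norm(pos, axis=1).max()
    if fit_to_sphere:
        pos = pos * (fit_fraction * head.brain_radius / rmax)
    elif rmax >= head.brain_radius:
        bad = np.flatnonzero(np.linalg.norm(pos, axis=1) >= head.brain_radius)
        raise ValueError(f"source vertices on/outside brain shell: {bad[:10].tolist()}")
    gain, worst = _gain_vectors(head, pos, montage.positions)
    if worst > 1e-8:
        warnings.warn(
            f"series truncated at order {head.series_order} with last-term "
            f"ratio {worst:.2e}", SeriesConvergenceWarning, stacklevel=2,
        )
    n_e, n_s = len(montage), space.n_sources
    matrix = gain.transpose(0, 1, 2).reshape(n_e, 3 * n_s)
    if average_reference:
        matrix = matrix - matrix.mean(axis=0, keepdims=True)
    return LeadField(matrix, list(montage.names), space, average_reference, pos)
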