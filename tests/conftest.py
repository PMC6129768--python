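"""Shared fixtures: sphere source spaces, montages, lead fields, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from slmcompare.forward import HeadModel, LeadField, compute_lead_field, make_standard_montage
from slmcompare.source_space import SourceSpace, build_graph, make_sphere_source_space


@pytest.fixture(scope="session")
def sphere162() -> SourceSpace:
    return make_sphere_source_space(2, 70.0)


@pytest.fixture(scope="session")
def sphere642() -> SourceSpace:
    return make_sphere_source_space(3, 70.0)


@pytest.fixture(scope="session")
def graph162(sphere162):
    return build_graph(sphere162)


@pytest.fixture(scope="session")
def graph642(sphere642):
    return build_graph(sphere642)


@pytest.fixture(scope="session")
def head() -> HeadModel:
    return HeadModel()


@pytest.fixture(scope="session")
def montage32():
    return make_standard_montage(32)


@pytest.fixture(scope="session")
def lead162(head, montage32, sphere162) -> LeadField:
    return compute_lead_field(head, montage32, sphere162)


@pytest.fixture(scope="session")
def lead642(head, montage32, sphere642) -> LeadField:
    return compute_lead_field(head, montage32, sphere642)


def tetrahedron_space(scale: float = 10.0) -> SourceSpace:
    """Smallest closed triangle mesh."""
    verts = scale * np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    hemi = np.where(verts[:, 0] < 0, "left", "right")
    return SourceSpace(verts, faces, hemi)


@pytest.fixture()
def tetra() -> SourceSpace:
    return tetrahedron_space()


# ---------------------------------------------------------------------------
# independent oracles


def homogeneous_sphere_potential(
    radius_mm: float,
    sigma: float,
    src_mm: np.ndarray,
    moment_nAm: np.ndarray,
    electrode_mm: np.ndarray,
) -> float:
    """Closed-form surface potential (µV) of a dipole in a homogeneous
    conducting sphere with insulating boundary.

    Derived by summing the generating functions of the Legendre series; used
    as the independent oracle for the multilayer series with equal
    conductivities.
    """
    R = radius_mm * 1e-3
    r0 = np.asarray(src_mm, float) * 1e-3
    re = np.asarray(electrode_mm, float) * 1e-3
    m = np.asarray(moment_nAm, float) * 1e-9
    b = np.linalg.norm(r0)
    f = b / R
    rb = r0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    ru = re / np.linalg.norm(re)
    x = float(np.clip(rb @ ru, -1.0, 1.0))
    s = np.sqrt(max(1.0 - x * x, 0.0))
    mr = float(m @ rb)
    mt = float(m @ ((ru - x * rb) / s)) if s > 1e-12 else 0.0
    rho = np.sqrt(1.0 - 2.0 * f * x + f * f)
    if f > 0:
        radial = 2.0 * (x - f) / rho**3 + (1.0 / rho - 1.0) / f
    else:
        radial = 3.0 * x
    tangential = 2.0 * s / rho**3 + s * (rho + 1.0) / (rho * (1.0 - f * x + rho))
    v = (radial * mr + tangential * mt) / (4.0 * np.pi * sigma * R**2)
    return float(v * 1e6)  # V -> µV


def dbscan_reachability_oracle(
    points: np.ndarray, eps: float, min_points: int
) -> tuple[list[set[int]], set[int], set[int]]:
    """Exhaustive density-reachability DBSCAN on a handful of points.

    Returns (core-point clusters, core points, noise points).  Core points
    have >= min_points neighbors within eps (self included); clusters are
    the connected components of core points under eps-adjacency; non-core
    points within eps of a core point are border points (cluster-assignable
    but excluded from the returned partition); the rest are noise.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbor = d <= eps
    core = {i for i in range(n) if neighbor[i].sum() >= min_points}
    clusters: list[set[int]] = []
    unvisited = set(core)
    while unvisited:
        seed_pt = unvisited.pop()
        comp = {seed_pt}
        frontier = [seed_pt]
        while frontier:
            i = frontier.pop()
            for j in core:
                if j not in comp and neighbor[i, j]:
                    comp.add(j)
                    frontier.append(j)
        unvisited -= comp
        clusters.append(comp)
    border = {
        i for i in range(n) if i not in core and any(neighbor[i, j] for j in core)
    }
    noise = set(range(n)) - core - border
    return clusters, core, noise


def holm_adjust_oracle(p_values: list[float]) -> list[float]:
    """Hand-rolled Bonferroni-Holm step-down adjustment."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
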