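"""Per-residue and per-pair observables: RMSF, distances, and SASA.

RMSF is computed about the window-mean position of an already aligned
trajectory; distances support atom–atom and (mass-weighted) center-of-mass
modes; solvent-accessible surface area uses the Shrake–Rupley construction
with a deterministic Fibonacci-spiral point set, so results are reproducible
without a random seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import AtomSelection, Trajectory, select


@dataclass
class ResidueProfile:
    residue_index: int
    value: float  # Å (RMSF) or Å² (SASA)
    window: tuple[int, int]


@dataclass
class DistanceSeries:
    spec_i: str
    spec_j: str
    values: np.ndarray  # Å per frame


def _window_slice(n_frames: int, window: tuple[int, int] | None) -> slice:
    if window is None:
        return slice(0, n_frames)
    a, b = window
    if not (0 <= a < b <= n_frames):
        raise ValueError(f"window [{a}, {b}) invalid for {n_frames} frames")
    return slice(a, b)


def rmsf(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    window: tuple[int, int] | None = None,
) -> list[ResidueProfile]:
    """Root-mean-square fluctuation per selected atom over a frame window.

    For each atom: sqrt(mean_t |r(t) − ⟨r⟩|²) with ⟨r⟩ the window-mean
    position. The trajectory is assumed aligned (rigid-body motion removed).
    """
    sl = _window_slice(traj.n_frames, window)
    if sl.stop - sl.start < 1:
        raise ValueError("empty RMSF window")
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    sub = traj.frames[sl][:, idx, :]
    mean = sub.mean(axis=0)
    msf = ((sub - mean) ** 2).sum(axis=2).mean(axis=0)
    win = (sl.start, sl.stop)
    return [
        ResidueProfile(
            residue_index=traj.structure.atoms[i].residue_index,
            value=float(np.sqrt(m)),
            window=win,
        )
        for i, m in zip(idx, msf)
    ]


def _resolve_group(traj: Trajectory, spec: str | AtomSelection) -> AtomSelection:
    if isinstance(spec, AtomSelection):
        if len(spec) == 0:
            raise ValueError(f"selection {spec.descriptor!r} resolves to no atoms")
        return spec
    return select(traj.structure, spec)


def distance_series(
    traj: Trajectory,
    spec_i: str | AtomSelection,
    spec_j: str | AtomSelection,
    mode: str = "atom-atom",
    window: tuple[int, int] | None = None,
) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms or group centroids.

    ``mode``: "atom-atom" (both specs must resolve to single atoms),
    "com-atom" (first spec is a mass-weighted centroid), or "com-com".
    """
    sel_i = _resolve_group(traj, spec_i)
    sel_j = _resolve_group(traj, spec_j)
    sl = _window_slice(traj.n_frames, window)
    masses = traj.structure.masses()

    def positions(sel: AtomSelection, as_com: bool) -> np.ndarray:
        pts = traj.frames[sl][:, sel.indices, :]
        if not as_com:
            if len(sel) != 1:
                raise ValueError(
                    f"selection {sel.descriptor!r} resolves to {len(sel)} atoms; "
                    "atom mode needs exactly one"
                )
            return pts[:, 0, :]
        w = masses[sel.indices]
        return (pts * w[None, :, None]).sum(axis=1) / w.sum()

    com_i = mode in ("com-atom", "com-com")
    com_j = mode == "com-com"
    if mode not in ("atom-atom", "com-atom", "com-com"):
        raise ValueError(f"unknown distance mode {mode!r}")
    pi = positions(sel_i, com_i)
    pj = positions(sel_j, com_j)
    values = np.linalg.norm(pi - pj, axis=1)
    return DistanceSeries(
        spec_i=sel_i.descriptor, spec_j=sel_j.descriptor, values=values
    )


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * k + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _neighbor_pairs(coords: np.ndarray, radii_exp: np.ndarray) -> list[np.ndarray]:
    """Per-atom candidate occluder lists.

    Brute force below 200 atoms; above that a scipy KD-tree query within the
    maximal sphere-overlap distance plays the role of a cell list.
    """
    n = coords.shape[0]
    rmax = radii_exp.max()
    if n < 200:
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        out = []
        for i in range(n):
            cutoff = (radii_exp[i] + rmax) ** 2
            nb = np.nonzero((d2[i] <= cutoff) & (np.arange(n) != i))[0]
            out.append(nb)
        return out
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    out = []
    for i in range(n):
        nb = tree.query_ball_point(coords[i], radii_exp[i] + rmax)
        out.append(np.array([j for j in nb if j != i], dtype=int))
    return out


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    selection: AtomSelection | np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Each atom is sampled with ``n_points`` Fibonacci-spiral points on its
    probe-expanded sphere; a point is exposed iff strictly outside every
    other atom's expanded sphere (ties count as buried, so fully coincident
    duplicate atoms contribute zero). Selection SASA is computed in the
    context of all atoms: non-selected atoms still occlude.

    Returns (per-atom SASA for the selected atoms, summed SASA).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    for i in range(n):
        if not radii[i] > 0:
            raise ValueError(f"atom index {i} has no positive vdW radius")
    if selection is None:
        idx = np.arange(n)
    elif isinstance(selection, AtomSelection):
        idx = selection.indices
    else:
        idx = np.asarray(selection, dtype=int)

    sphere = fibonacci_sphere(n_points)
    radii_exp = radii + probe_radius
    neighbors = _neighbor_pairs(coords, radii_exp)

    areas = np.zeros(idx.size)
    for k, i in enumerate(idx):
        pts = coords[i] + radii_exp[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        nb = neighbors[i]
        for j in nb:
            if not exposed.any():
                break
            d2 = ((pts[exposed] - coords[j]) ** 2).sum(axis=1)
            # strictly-outside rule: points on/inside a neighbor sphere are
            # buried (tolerance absorbs rounding so exact ties stay buried)
            r2 = radii_exp[j] ** 2
            still = d2 > r2 * (1.0 + 1e-9)
            exp_idx = np.nonzero(exposed)[0]
            exposed[exp_idx[~still]] = False
        frac = exposed.sum() / n_points
        areas[k] = 4.0 * np.pi * radii_exp[i] ** 2 * frac
    return areas, float(areas.sum())


def sasa_series(
    traj: Trajectory,
    selection: AtomSelection,
    window: tuple[int, int] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    reference_value: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Per-frame selection SASA over a window.

    If ``reference_value`` is given, also returns the fraction of frames whose
    SASA strictly exceeds it (the solvent-exposure occupancy of the
    selection relative to, e.g., its crystal-structure value).
    """
    sl = _window_slice(traj.n_frames, window)
    radii = traj.structure.radii()
    values = np.array(
        [
            sasa(frame, radii, selection, probe_radius, n_points)[1]
            for frame in traj.frames[sl]
        ]
    )
    exceed = None
    if reference_value is not None:
        exceed = float((values > reference_value).mean())
    return values, exceed


def write_profile(path, xs, ys, header: str = "index value") -> None:
    """Two-column delimited text with a one-line header."""
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for x, y in zip(xs, ys):
            fh.write(f"{x} {y:.10g}\n")
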