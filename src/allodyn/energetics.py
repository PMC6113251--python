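"""Single-trajectory MM-GBSA binding free energy and quasi-harmonic entropy.

The binding free energy of a two-chain complex is estimated from one
trajectory of the whole complex:

    G_TOT = H_MM + G_solv - T*dS_conf
    dG_bind = G_TOT(complex) - [G_TOT(receptor) + G_TOT(ligand)]

with H_MM the gas-phase molecular-mechanics energy (bonded + Coulomb +
Lennard-Jones) and G_solv = polar (generalized Born) + nonpolar (SASA-linear)
solvation. Receptor and ligand frames are decomposed out of the same complex
trajectory, so every intra-subset bonded term cancels exactly in the
difference — the bonded contribution to dG_bind is identically zero.

Two input routes are supported: per-frame energy-term tables written by an
external engine (the format-stable path), and a self-contained desk-scale
evaluator (Coulomb / LJ 12-6 / Still-type GB / gamma*SASA+b) for synthetic
systems. Configurational entropy uses the quasi-harmonic approximation on
the mass-weighted coordinate covariance (Andricioaei–Karplus by default,
Schlitter behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import sasa as _sasa
from .trajio import AtomSelection, Trajectory

COULOMB_CONSTANT = 332.0636  # kcal*Å/(mol*e²)

# physical constants for quasi-harmonic entropy
_KB_J = 1.380649e-23  # J/K
_HBAR = 1.0545718176e-34  # J*s
_AMU_A2_TO_KG_M2 = 1.66053906660e-27 * 1e-20
_R_KCAL = 1.987204259e-3  # kcal/(mol*K)

TERM_COLUMNS = ["E_bonded", "E_elec", "E_vdw", "G_polar", "G_np"]


@dataclass
class EnergyDecomposition:
    """Per-frame energy terms for one subset, with window aggregates."""

    label: str  # complex | receptor | ligand
    terms: pd.DataFrame  # columns: frame + TERM_COLUMNS
    window: tuple[int, int]

    @property
    def n_frames(self) -> int:
        return len(self.terms)

    def mean(self) -> pd.Series:
        return self.terms[TERM_COLUMNS].mean()

    def std(self) -> pd.Series:
        return self.terms[TERM_COLUMNS].std(ddof=1)


@dataclass
class BindingFreeEnergy:
    dG_bind: float
    dG_bind_std: float
    terms: dict  # name -> (mean, std) for dE_elec, dE_vdw, dG_solv, dG_solv_np, dG_solv_polar, dE_bonded
    TdS_conf: float | None = None
    per_frame: pd.DataFrame | None = None


@dataclass
class EntropyResult:
    S_conf: float  # kcal/(mol*K)
    TS: float  # kcal/mol
    temperature: float
    eigenvalues: np.ndarray  # amu*Å², descending
    n_excluded: int


# ---------------------------------------------------------------------------
# desk-scale molecular-mechanics terms
# ---------------------------------------------------------------------------

def _subset_arrays(structure, subset: AtomSelection):
    idx = subset.indices
    atoms = [structure.atoms[i] for i in idx]
    q = np.array([a.charge for a in atoms])
    rmin_half = np.array([a.vdw_radius for a in atoms])
    eps = np.array([a.lj_epsilon for a in atoms])
    missing = [a.serial for a, r in zip(atoms, rmin_half) if not r > 0]
    if missing:
        raise ValueError(f"atoms with serial {missing} missing vdW/LJ radius")
    return idx, q, rmin_half, eps


def mm_terms(
    coords: np.ndarray,
    structure,
    subset: AtomSelection,
    dielectric: float = 1.0,
) -> tuple[float, float]:
    """Gas-phase Coulomb and Lennard-Jones energy of one subset (kcal/mol).

    All intra-subset pairs, no cutoff; Coulomb 332.0636*q_i*q_j/(eps*r) with
    r in Å and charges in e; LJ 12-6 from per-atom (Rmin/2, epsilon) with
    Lorentz–Berthelot combining. Bonded terms are zero for the rigid toy
    fragments this evaluator targets (or come from an external table).
    """
    idx, q, rmin_half, eps = _subset_arrays(structure, subset)
    pts = np.asarray(coords, dtype=float)[idx]
    n = len(idx)
    if n < 2:
        return 0.0, 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    if np.any(rij <= 0):
        bad = np.argwhere(rij <= 0)[0][0]
        raise ValueError(
            f"zero distance between distinct atoms (pair index {bad}); "
            "overlapping coordinates"
        )
    e_elec = float((COULOMB_CONSTANT * np.outer(q, q)[iu] / (dielectric * rij)).sum())
    rmin_ij = (rmin_half[:, None] + rmin_half[None, :])[iu]
    eps_ij = np.sqrt(np.outer(eps, eps))[iu]
    s6 = (rmin_ij / rij) ** 6
    e_vdw = float((eps_ij * (s6**2 - 2.0 * s6)).sum())
    return e_elec, e_vdw


def nonpolar_solvation(
    coords: np.ndarray,
    structure,
    subset: AtomSelection,
    gamma: float = 0.00542,
    b: float = 0.92,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """SASA-linear nonpolar solvation, gamma*SASA + b (kcal/mol).

    The subset is treated as an isolated molecule: only its own atoms
    occlude, matching the single-trajectory decomposition where receptor and
    ligand are extracted from the complex frames.
    """
    if len(subset) == 0:
        raise ValueError("nonpolar solvation of an empty subset is undefined")
    idx = subset.indices
    pts = np.asarray(coords, dtype=float)[idx]
    radii = np.array([structure.atoms[i].vdw_radius for i in idx])
    _, total = _sasa(pts, radii, probe_radius=probe_radius, n_points=n_points)
    return gamma * total + b


def polar_solvation(
    coords: np.ndarray,
    structure,
    subset: AtomSelection,
    born_radii: np.ndarray | None = None,
    solvent_dielectric: float = 78.5,
) -> float:
    """Still-type generalized-Born polar solvation energy (kcal/mol).

    dG_GB = -(1/2)(1 - 1/eps_w) * 332.0636 * sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r_ij² + a_i a_j exp(-r_ij²/(4 a_i a_j))); the double sum
    includes i = j self (Born) terms. Born radii default to the per-atom vdW
    radius minus a 0.09 Å offset.
    """
    idx = subset.indices
    atoms = [structure.atoms[i] for i in idx]
    q = np.array([a.charge for a in atoms])
    if born_radii is None:
        a_born = np.array([a.vdw_radius - 0.09 for a in atoms])
    else:
        a_born = np.asarray(born_radii, dtype=float)[idx] if len(born_radii) == len(
            structure.atoms
        ) else np.asarray(born_radii, dtype=float)
    if np.any(a_born <= 0):
        bad = [atoms[i].serial for i in np.nonzero(a_born <= 0)[0]]
        raise ValueError(f"nonpositive Born radius for atom serial(s) {bad}")
    pts = np.asarray(coords, dtype=float)[idx]
    diff = pts[:, None, :] - pts[None, :, :]
    r2 = (diff**2).sum(axis=2)
    aa = np.outer(a_born, a_born)
    f_gb = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    energy = (np.outer(q, q) / f_gb).sum()
    return float(-0.5 * (1.0 - 1.0 / solvent_dielectric) * COULOMB_CONSTANT * energy)


# ---------------------------------------------------------------------------
# decomposition and binding free energy
# ---------------------------------------------------------------------------

def read_term_table(path) -> pd.DataFrame:
    """Per-frame term table: header 'frame E_bonded E_elec E_vdw G_polar G_np'."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in ["frame", *TERM_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: term table missing column(s) {missing}")
    return df


def write_term_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("frame " + " ".join(TERM_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write(
                f"{int(row['frame'])} "
                + " ".join(f"{row[c]:.10g}" for c in TERM_COLUMNS)
                + "\n"
            )


def _validate_subsets(complex_sel, receptor_sel, ligand_sel):
    comp = set(complex_sel.indices.tolist())
    rec = set(receptor_sel.indices.tolist())
    lig = set(ligand_sel.indices.tolist())
    if not rec or not lig:
        raise ValueError("receptor and ligand subsets must be non-empty")
    if rec & lig:
        raise ValueError("receptor and ligand selections overlap")
    if rec | lig != comp:
        raise ValueError("receptor + ligand must partition the complex selection")


def decompose_single_trajectory(
    traj: Trajectory,
    complex_sel: AtomSelection,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    window: tuple[int, int] | None = None,
    term_source: str = "computed",
    tables: dict | None = None,
    born_radii: np.ndarray | None = None,
    solvent_dielectric: float = 78.5,
    gamma: float = 0.00542,
    b: float = 0.92,
    sasa_points: int = 960,
) -> dict[str, EnergyDecomposition]:
    """Per-frame energy terms for complex / receptor / ligand from one trajectory.

    In ``computed`` mode every subset's terms are evaluated on the same
    frames with the desk-scale evaluator (E_bonded = 0 for these rigid toy
    fragments). In ``table`` mode three externally produced per-frame tables
    keyed "complex", "receptor", "ligand" are aggregated instead.
    """
    _validate_subsets(complex_sel, receptor_sel, ligand_sel)
    if window is None:
        window = (0, traj.n_frames)
    a, bw = window
    if not (0 <= a < bw <= traj.n_frames):
        raise ValueError(f"window [{a}, {bw}) invalid for {traj.n_frames} frames")

    if term_source == "table":
        if tables is None or set(tables) != {"complex", "receptor", "ligand"}:
            raise ValueError(
                "table mode needs tables for exactly complex/receptor/ligand"
            )
        out = {}
        lengths = {k: len(v) for k, v in tables.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"term tables have mismatched frame counts {lengths}")
        for label, df in tables.items():
            out[label] = EnergyDecomposition(
                label=label, terms=df.reset_index(drop=True), window=window
            )
        return out
    if term_source != "computed":
        raise ValueError(f"unknown term source {term_source!r}")

    subsets = {"complex": complex_sel, "receptor": receptor_sel, "ligand": ligand_sel}
    out = {}
    for label, sel in subsets.items():
        rows = []
        for f in range(a, bw):
            coords = traj.frames[f]
            e_elec, e_vdw = mm_terms(coords, traj.structure, sel)
            g_np = nonpolar_solvation(
                coords, traj.structure, sel, gamma=gamma, b=b, n_points=sasa_points
            )
            g_pol = polar_solvation(
                coords,
                traj.structure,
                sel,
                born_radii=born_radii,
                solvent_dielectric=solvent_dielectric,
            )
            rows.append(
                {
                    "frame": f,
                    "E_bonded": 0.0,
                    "E_elec": e_elec,
                    "E_vdw": e_vdw,
                    "G_polar": g_pol,
                    "G_np": g_np,
                }
            )
        out[label] = EnergyDecomposition(
            label=label, terms=pd.DataFrame(rows), window=window
        )
    return out


def binding_free_energy(
    decompositions: dict[str, EnergyDecomposition],
    include_entropy: bool = False,
    TdS_conf: float | None = None,
    temperature: float = 298.0,
) -> BindingFreeEnergy:
    """Termwise dX = X_complex - (X_receptor + X_ligand) and dG_bind.

    The differences are formed frame-by-frame and then averaged: in the
    single-trajectory scheme the three subsets are evaluated on the same
    frames and are perfectly correlated, so propagating subset standard
    deviations in quadrature would be wrong. dG_bind = dH_MM + dG_solv,
    minus T*ddS_conf only when entropy is requested.
    """
    for key in ("complex", "receptor", "ligand"):
        if key not in decompositions:
            raise ValueError(f"missing decomposition {key!r}")
    c, r, l = (decompositions[k] for k in ("complex", "receptor", "ligand"))
    if not (c.window == r.window == l.window and c.n_frames == r.n_frames == l.n_frames):
        raise ValueError("decompositions cover different windows")

    delta = pd.DataFrame(
        {
            col: c.terms[col].to_numpy()
            - (r.terms[col].to_numpy() + l.terms[col].to_numpy())
            for col in TERM_COLUMNS
        }
    )
    delta["dH_MM"] = delta["E_bonded"] + delta["E_elec"] + delta["E_vdw"]
    delta["dG_solv"] = delta["G_polar"] + delta["G_np"]
    delta["dG_bind"] = delta["dH_MM"] + delta["dG_solv"]

    def ms(col):
        v = delta[col]
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    terms = {
        "dE_bonded": ms("E_bonded"),
        "dE_elec": ms("E_elec"),
        "dE_vdw": ms("E_vdw"),
        "dG_solv": ms("dG_solv"),
        "dG_solv_np": ms("G_np"),
        "dG_solv_polar": ms("G_polar"),
    }
    dg_mean, dg_std = ms("dG_bind")
    tds = None
    if include_entropy:
        if TdS_conf is None:
            raise ValueError("include_entropy=True requires TdS_conf")
        tds = float(TdS_conf)
        dg_mean -= tds
    return BindingFreeEnergy(
        dG_bind=dg_mean,
        dG_bind_std=dg_std,
        terms=terms,
        TdS_conf=tds,
        per_frame=delta,
    )


def format_summary(bfe: BindingFreeEnergy) -> str:
    """Human-readable mean ± std table of the binding-energy contributions."""
    rows = [("dG_bind", bfe.dG_bind, bfe.dG_bind_std)]
    order = ["dE_elec", "dE_vdw", "dG_solv", "dG_solv_np", "dG_solv_polar"]
    rows += [(k, *bfe.terms[k]) for k in order]
    lines = ["Contribution      mean ± std (kcal/mol)"]
    for name, m, s in rows:
        lines.append(f"{name:<16s} {m:10.2f} ± {s:.2f}")
    if bfe.TdS_conf is not None:
        lines.append(f"{'T*dS_conf':<16s} {bfe.TdS_conf:10.2f}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# quasi-harmonic configurational entropy
# ---------------------------------------------------------------------------

def mode_entropy(alpha: float) -> float:
    """Per-mode harmonic-oscillator entropy in units of k_B.

    alpha = hbar*omega/(k_B*T). Vanishes as alpha -> inf (stiff/static mode).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha > 700.0:
        return 0.0
    return float(alpha / np.expm1(alpha) - np.log1p(-np.exp(-alpha)))


def quasiharmonic_entropy(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    window: tuple[int, int] | None = None,
    temperature: float = 298.0,
    n_exclude: int = 6,
    method: str = "andricioaei-karplus",
) -> EntropyResult:
    """Configurational entropy from the mass-weighted coordinate covariance.

    Eigenvalues sigma² (amu*Å²) of the mass-weighted covariance define
    quasi-harmonic frequencies omega = sqrt(k_B*T/sigma²); each mode
    contributes the harmonic-oscillator entropy at that frequency
    (Andricioaei–Karplus; the Schlitter upper-bound formula is available as
    ``method="schlitter"``). The ``n_exclude`` smallest-eigenvalue modes —
    residual rigid-body motion after alignment — are dropped. The trajectory
    should already be aligned.
    """
    if window is None:
        window = (0, traj.n_frames)
    a, b = window
    if not (0 <= a < b <= traj.n_frames):
        raise ValueError(f"window [{a}, {b}) invalid for {traj.n_frames} frames")
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    sub = traj.frames[a:b][:, idx, :]
    f, n, _ = sub.shape
    masses = traj.structure.masses()[idx]
    if np.any(masses <= 0):
        raise ValueError("all selected atoms need positive masses")

    sqrt_m = np.repeat(np.sqrt(masses), 3)
    x = sub.reshape(f, 3 * n) * sqrt_m[None, :]
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / f  # amu*Å²
    evals = np.linalg.eigvalsh(cov)[::-1]  # descending
    evals = np.clip(evals, 0.0, None)
    if f < 3 * n:
        import logging

        logging.getLogger(__name__).warning(
            "quasi-harmonic covariance is rank-deficient: %d frames < 3N=%d",
            f,
            3 * n,
        )

    kept = evals[: max(0, len(evals) - n_exclude)]
    kt = _KB_J * temperature
    s_over_kb = 0.0
    for sigma2 in kept:
        sigma2_si = sigma2 * _AMU_A2_TO_KG_M2
        if sigma2_si <= 0:
            continue  # static mode: zero entropy in the stiff limit
        alpha = _HBAR / np.sqrt(kt * sigma2_si)
        if method == "andricioaei-karplus":
            s_over_kb += mode_entropy(alpha)
        elif method == "schlitter":
            s_over_kb += 0.5 * np.log1p(np.e**2 / alpha**2)
        else:
            raise ValueError(f"unknown entropy method {method!r}")
    s_conf = _R_KCAL * s_over_kb  # kcal/(mol*K)
    return EntropyResult(
        S_conf=s_conf,
        TS=s_conf * temperature,
        temperature=temperature,
        eigenvalues=evals,
        n_excluded=min(n_exclude, len(evals)),
    )


def alpha_for_sigma2(sigma2_amu_A2: float, temperature: float = 298.0) -> float:
    """hbar*omega/(k_B*T) for a mass-weighted covariance eigenvalue (amu*Å²)."""
    kt = _KB_J * temperature
    return float(_HBAR / np.sqrt(kt * sigma2_amu_A2 * _AMU_A2_TO_KG_M2))
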