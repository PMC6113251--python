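"""Synthetic trajectories, complexes, and energy tables with known ground truth.

The generator emulates the statistical structure the analyses assume in a
two-chain Cα-level complex: Gaussian fluctuations about a reference geometry
with a planted block correlation matrix (so the analytic cross-correlation
is known exactly), scripted residue-pair contacts with deterministic
occupancy schedules (so 75%-type thresholds are testable at the boundary),
and per-frame energy-term tables with planted term differences. It performs
no physics — no integrator, no force field — only controlled statistics.

Displacements are isotropic per residue: the same residue–residue
correlation matrix drives x, y and z independently, scaled by per-residue
amplitudes. Under the 3-D dot-product correlation definition the analytic
C_ij then equals the planted scalar correlation, keeping the oracle closed
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._elements import ELEMENT_MASS, ELEMENT_VDW
from .energetics import TERM_COLUMNS
from .trajio import Atom, Structure, Trajectory


@dataclass
class CovarianceBlock:
    """A set of residues moving together with a common internal correlation."""

    members: list[int]  # global residue indices (0-based)
    within: float  # pairwise correlation inside the block
    amplitude: float = 0.5  # per-axis fluctuation sigma, Å


@dataclass
class ContactPlan:
    """A scripted residue pair switching between contact and apart distances."""

    res_i: int
    res_j: int
    occupancy: float  # target fraction of frames in contact
    contact_distance: float = 4.0
    noncontact_distance: float = 9.0


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic trajectory."""

    chain_sizes: dict[str, int]  # ordered chain id -> number of residues
    n_frames: int = 1000
    seed: int = 0
    blocks: list[CovarianceBlock] = field(default_factory=list)
    between: float = 0.0  # correlation between residues of different blocks
    default_amplitude: float = 0.3  # per-axis sigma for unassigned residues, Å
    contacts: list[ContactPlan] = field(default_factory=list)
    geometry: str = "helix"  # helix | clustered
    contact_jitter: float = 0.01  # per-axis sigma for scripted residues, Å


@dataclass
class GroundTruth:
    """Analytic quantities the generator guarantees about its output."""

    correlation: np.ndarray  # planted C_ij, n_res x n_res
    partition: dict  # residue index -> planted community id
    chain_of: dict  # residue index -> chain id
    spectrum: np.ndarray | None  # planted 3N covariance eigenvalues (Å²), descending
    contact_occupancy: dict  # (res_i, res_j) -> achieved occupancy
    reference: np.ndarray  # n_res x 3 reference coordinates


def _total_residues(spec: SyntheticSpec) -> int:
    return sum(spec.chain_sizes.values())


def _build_reference(spec: SyntheticSpec) -> np.ndarray:
    """Reference Cα geometry.

    ``helix``: one gentle 3-D helix with 3.8 Å spacing between consecutive
    residues — consecutive pairs are bonded-neighbor-like, nonconsecutive
    pairs are well separated, chains offset along x.
    ``clustered``: each covariance block (and each leftover chain segment)
    is a compact 3-D grid with 3.0 Å cell edge, serpentine-ordered so
    consecutive residues sit in adjacent cells. Face neighbors (3.0 Å) and
    face diagonals (4.24 Å) both fall inside a 4.5 Å contact cutoff, so each
    block forms a well-connected contact graph even after the
    consecutive-residue exclusion. Clusters are laid out along x with a
    3.6 Å boundary gap, so facing residues of adjacent clusters form a few
    bridge contacts — the between-block edges community detection must cut.
    """
    n = _total_residues(spec)
    coords = np.zeros((n, 3))
    if spec.geometry == "helix":
        offset = 0.0
        start = 0
        for chain, size in spec.chain_sizes.items():
            radius, spacing = 8.0, 3.8
            dtheta = 0.25  # rad per residue; gentle winding
            arc = radius * dtheta
            rise = np.sqrt(max(spacing**2 - arc**2, 0.25))
            for k in range(size):
                t = k * dtheta
                coords[start + k] = [
                    offset + radius * np.cos(t),
                    radius * np.sin(t),
                    k * rise,
                ]
            offset += 3.0 * radius
            start += size
    elif spec.geometry == "clustered":
        groups: list[list[int]] = []
        assigned: set[int] = set()
        for blk in spec.blocks:
            groups.append(list(blk.members))
            assigned.update(blk.members)
        start = 0
        for chain, size in spec.chain_sizes.items():
            rest = [r for r in range(start, start + size) if r not in assigned]
            if rest:
                groups.append(rest)
            start += size
        spacing, boundary_gap = 3.0, 3.6
        origin_x = 0.0
        for g, members in enumerate(groups):
            m = len(members)
            side = int(np.ceil(m ** (1.0 / 3.0)))
            origin = np.array([origin_x, 0.0, 0.0])
            origin_x += spacing * (side - 1) + boundary_gap
            for k, res in enumerate(members):
                iz, rem = divmod(k, side * side)
                iy, ix = divmod(rem, side)
                # serpentine: alternate x direction within each row,
                # y direction within each layer -> consecutive cells adjacent
                if iy % 2 == 1:
                    ix = side - 1 - ix
                if iz % 2 == 1:
                    iy = side - 1 - iy
                coords[res] = origin + spacing * np.array([ix, iy, iz])
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return coords


def planted_correlation(spec: SyntheticSpec) -> np.ndarray:
    """The analytic residue–residue correlation matrix the plan implies."""
    n = _total_residues(spec)
    block_of = np.full(n, -1)
    for b, blk in enumerate(spec.blocks):
        for r in blk.members:
            if block_of[r] != -1:
                raise ValueError(f"residue {r} appears in more than one block")
            if not (0 <= r < n):
                raise ValueError(f"block residue {r} out of range [0, {n})")
            block_of[r] = b
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = block_of[i], block_of[j]
            if bi == -1 or bj == -1:
                val = 0.0
            elif bi == bj:
                val = spec.blocks[bi].within
            else:
                val = spec.between
            c[i, j] = c[j, i] = val
    return c


def _validate_psd(spec: SyntheticSpec, c: np.ndarray) -> None:
    evals = np.linalg.eigvalsh(c)
    if evals[0] < -1e-10:
        # localize: test every pair of blocks for a PSD violation
        for a in range(len(spec.blocks)):
            for b in range(a + 1, len(spec.blocks)):
                idx = list(spec.blocks[a].members) + list(spec.blocks[b].members)
                sub = c[np.ix_(idx, idx)]
                if np.linalg.eigvalsh(sub)[0] < -1e-10:
                    raise ValueError(
                        f"planted covariance is not positive semi-definite: "
                        f"block pair ({a}, {b}) with within-correlations "
                        f"({spec.blocks[a].within}, {spec.blocks[b].within}) and "
                        f"between={spec.between} is infeasible"
                    )
        raise ValueError(
            f"planted covariance is not positive semi-definite "
            f"(min eigenvalue {evals[0]:.3e})"
        )


def _amplitudes(spec: SyntheticSpec) -> np.ndarray:
    n = _total_residues(spec)
    amp = np.full(n, spec.default_amplitude)
    for blk in spec.blocks:
        amp[list(blk.members)] = blk.amplitude
    return amp


def _ca_structure(spec: SyntheticSpec, coords: np.ndarray) -> Structure:
    atoms = []
    serial = 1
    res_index = 0
    for chain, size in spec.chain_sizes.items():
        for k in range(size):
            atoms.append(
                Atom(
                    serial=serial,
                    name="CA",
                    element="C",
                    residue_index=res_index,
                    residue_name="GLY",
                    residue_seq=k + 1,
                    chain_id=chain,
                    mass=ELEMENT_MASS["C"],
                    vdw_radius=ELEMENT_VDW["C"],
                )
            )
            serial += 1
            res_index += 1
    return Structure(atoms=atoms, coordinates=coords.copy())


def _contact_schedule(occupancy: float, n_frames: int) -> np.ndarray:
    """Deterministic in-contact mask: the first round(p*F) frames."""
    k = int(round(occupancy * n_frames))
    mask = np.zeros(n_frames, dtype=bool)
    mask[:k] = True
    return mask


def generate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Draw a trajectory with the planted covariance and scripted contacts.

    Correlated Gaussian displacements come from a symmetric factor of the
    validated plan, drawn independently per Cartesian axis (seeded).
    Contact-plan residues are excluded from covariance blocks; their
    coordinates are scripted (pair axis fixed, occupancy schedule exact)
    with only a small isotropic jitter so no atom is perfectly frozen.
    """
    n = _total_residues(spec)
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    scripted = set()
    for cp in spec.contacts:
        if not (0.0 <= cp.occupancy <= 1.0):
            raise ValueError(f"contact occupancy {cp.occupancy} outside [0, 1]")
        scripted.update((cp.res_i, cp.res_j))
    for blk in spec.blocks:
        overlap = scripted & set(blk.members)
        if overlap:
            raise ValueError(
                f"residues {sorted(overlap)} are both in a covariance block "
                "and a contact plan"
            )

    corr = planted_correlation(spec)
    _validate_psd(spec, corr)
    amp = _amplitudes(spec)
    ref = _build_reference(spec)

    rng = np.random.default_rng(spec.seed)
    # per-axis covariance: D R D with D = diag(amplitudes); factor via
    # eigendecomposition so exactly semi-definite plans (zero amplitudes,
    # perfect correlations) are handled without jitter
    cov = corr * np.outer(amp, amp)
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((spec.n_frames, n, 3))
    disp = np.einsum("ij,fja->fia", factor, z)
    frames = ref[None, :, :] + disp

    achieved: dict = {}
    chain_of: dict = {}
    start = 0
    for chain, size in spec.chain_sizes.items():
        for k in range(size):
            chain_of[start + k] = chain
        start += size

    for cp in spec.contacts:
        u = ref[cp.res_j] - ref[cp.res_i]
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        mask = _contact_schedule(cp.occupancy, spec.n_frames)
        jitter_i = spec.contact_jitter * rng.standard_normal((spec.n_frames, 3))
        jitter_j = spec.contact_jitter * rng.standard_normal((spec.n_frames, 3))
        d = np.where(mask, cp.contact_distance, cp.noncontact_distance)
        frames[:, cp.res_i, :] = ref[cp.res_i] + jitter_i
        # jitter applied along the pair axis is removed so the scheduled
        # distance is exact to within the perpendicular second-order term
        perp_j = jitter_j - (jitter_j @ u)[:, None] * u[None, :]
        frames[:, cp.res_j, :] = ref[cp.res_i] + d[:, None] * u[None, :] + perp_j
        achieved[(cp.res_i, cp.res_j)] = float(mask.mean())

    partition = {}
    next_id = len(spec.blocks)
    for r in range(n):
        for b, blk in enumerate(spec.blocks):
            if r in blk.members:
                partition[r] = b
                break
        else:
            partition[r] = next_id
            next_id += 1

    spectrum = None
    if not spec.contacts:
        evals = np.linalg.eigvalsh(cov)[::-1]
        spectrum = np.repeat(evals, 3)
        spectrum.sort()
        spectrum = spectrum[::-1].copy()

    structure = _ca_structure(spec, ref)
    traj = Trajectory(structure=structure, frames=frames)
    truth = GroundTruth(
        correlation=corr,
        partition=partition,
        chain_of=chain_of,
        spectrum=spectrum,
        contact_occupancy=achieved,
        reference=ref,
    )
    return traj, truth


def generate_complex(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """A two-chain complex trajectory; blocks may span the chain interface.

    Identical to :func:`generate_trajectory` but requires at least two
    chains (receptor/ligand), so a covariance block whose members fall in
    both chains plants a known interface community.
    """
    if len(spec.chain_sizes) < 2:
        raise ValueError("a complex needs at least two chains")
    if any(size < 1 for size in spec.chain_sizes.values()):
        raise ValueError("every chain must be non-empty")
    return generate_trajectory(spec)


def interface_blocks(spec: SyntheticSpec) -> list[int]:
    """Indices of planted blocks whose members span more than one chain."""
    bounds = []
    start = 0
    for chain, size in spec.chain_sizes.items():
        bounds.append((chain, start, start + size))
        start += size

    def chain_for(r: int) -> str:
        for chain, a, b in bounds:
            if a <= r < b:
                return chain
        raise ValueError(f"residue {r} out of range")

    out = []
    for b, blk in enumerate(spec.blocks):
        chains = {chain_for(r) for r in blk.members}
        if len(chains) > 1:
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# energy-table fixtures
# ---------------------------------------------------------------------------

def generate_energy_tables(
    n_frames: int,
    seed: int = 0,
    delta_means: dict | None = None,
    delta_stds: dict | None = None,
    base_level: float = -100.0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Three per-frame term tables with a planted termwise difference.

    The receptor and ligand tables are seeded noisy baselines; the complex
    table is their sum plus a per-frame difference series with the requested
    mean and standard deviation per term. Bonded columns are constructed so
    the bonded difference is exactly zero, as the single-trajectory scheme
    guarantees. Returns the tables and the analytic difference statistics
    (including the implied binding free energy mean).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    delta_means = dict(delta_means or {})
    delta_stds = dict(delta_stds or {})
    for term in TERM_COLUMNS:
        delta_means.setdefault(term, 0.0)
        delta_stds.setdefault(term, 0.0)
    if delta_means["E_bonded"] != 0.0 or delta_stds["E_bonded"] != 0.0:
        raise ValueError("the bonded difference is structurally zero; do not plant one")

    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    rec = pd.DataFrame({"frame": frames})
    lig = pd.DataFrame({"frame": frames})
    comp = pd.DataFrame({"frame": frames})
    deltas = {}
    for term in TERM_COLUMNS:
        if term == "E_bonded":
            # constant, exactly representable values so the bonded difference
            # cancels to machine zero, as the single-trajectory scheme demands
            rec[term] = np.full(n_frames, base_level)
            lig[term] = np.full(n_frames, base_level / 2)
            comp[term] = rec[term] + lig[term]
            deltas[term] = np.zeros(n_frames)
            continue
        rec[term] = base_level + rng.normal(0.0, 1.0, n_frames)
        lig[term] = base_level / 2 + rng.normal(0.0, 1.0, n_frames)
        d = delta_means[term] + delta_stds[term] * rng.standard_normal(n_frames)
        comp[term] = rec[term] + lig[term] + d
        deltas[term] = d
    analytic = {
        term: (delta_means[term], delta_stds[term]) for term in TERM_COLUMNS
    }
    analytic["dG_bind_mean"] = float(
        sum(delta_means[t] for t in TERM_COLUMNS)
    )
    analytic["delta_series"] = deltas
    return {"complex": comp, "receptor": rec, "ligand": lig}, analytic


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as delimited text for external inspection."""
    with open(path, "w") as fh:
        fh.write("# section residue community chain\n")
        for r in sorted(truth.partition):
            fh.write(f"node {r} {truth.partition[r]} {truth.chain_of[r]}\n")
        fh.write("# section correlation (row per residue)\n")
        for row in truth.correlation:
            fh.write("corr " + " ".join(f"{v:.6g}" for v in row) + "\n")
        for (i, j), occ in sorted(truth.contact_occupancy.items()):
            fh.write(f"contact {i} {j} {occ:.6g}\n")
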