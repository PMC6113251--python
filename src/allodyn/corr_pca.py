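"""Dynamic cross-correlation and Cartesian principal component analysis.

The cross-correlation matrix is the normalized covariance of atomic
displacements about the window-mean structure,

    C_ij = <dr_i . dr_j> / sqrt(<dr_i . dr_i> <dr_j . dr_j>),

with the full 3-D dot product in the numerator and population averages over
the frame window. PCA eigendecomposes the 3N x 3N covariance of the
concatenated Cartesian coordinates; the information content of component n
is its eigenvalue's share of the total, I_n = lambda_n / sum(lambda).
Both assume rigid-body motion has been removed (align_trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import AtomSelection, Trajectory


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray  # N_sel x N_sel, dimensionless
    selection: AtomSelection
    window: tuple[int, int]
    mean_structure: np.ndarray  # N_sel x 3, Å


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # Å², descending, length 3N
    eigenvectors: np.ndarray  # 3N x 3N, columns orthonormal
    information: np.ndarray  # I_n, sums to 1
    projections: np.ndarray  # F x K, Å
    mean_structure: np.ndarray  # N x 3


def _window_frames(traj: Trajectory, selection, window):
    if window is None:
        window = (0, traj.n_frames)
    a, b = window
    if not (0 <= a < b <= traj.n_frames):
        raise ValueError(f"window [{a}, {b}) invalid for {traj.n_frames} frames")
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    return traj.frames[a:b][:, idx, :], (a, b), idx


def cross_correlation(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    window: tuple[int, int] | None = None,
) -> CorrelationMatrix:
    """Normalized displacement covariance over a frame window.

    Displacements are taken from the window-mean position of each atom;
    averages are population means over the window. A zero-variance (frozen)
    atom makes the normalization singular and raises ``ValueError`` — it
    almost always indicates an upstream selection or alignment bug.
    """
    sub, win, idx = _window_frames(traj, selection, window)
    if sub.shape[0] < 2:
        raise ValueError("cross-correlation needs a window of at least 2 frames")
    mean = sub.mean(axis=0)
    disp = sub - mean  # F x N x 3
    # <dr_i . dr_j>: contract frame and Cartesian axes
    cov = np.einsum("fia,fja->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov)
    zero = np.nonzero(var <= 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance atom(s) at selected position(s) {zero.tolist()} "
            f"(atom indices {[int(idx[z]) for z in zero]})"
        )
    denom = np.sqrt(np.outer(var, var))
    c = cov / denom
    np.fill_diagonal(c, 1.0)
    sel = (
        selection
        if selection is not None
        else AtomSelection(indices=idx, descriptor="all")
    )
    return CorrelationMatrix(matrix=c, selection=sel, window=win, mean_structure=mean)


def pca(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    window: tuple[int, int] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Cartesian PCA of the selected coordinates over a frame window.

    Eigenvalues are sorted descending with ties broken by original order;
    each eigenvector's sign is fixed so its largest-magnitude coefficient is
    positive, making projections reproducible. Projections are the centered
    frame coordinates dotted onto the first ``n_components`` eigenvectors
    (default: all 3N).
    """
    sub, win, idx = _window_frames(traj, selection, window)
    f, n, _ = sub.shape
    if f < 2:
        raise ValueError("PCA needs at least 2 frames")
    three_n = 3 * n
    if n_components is None:
        n_components = three_n
    if not (1 <= n_components <= three_n):
        raise ValueError(f"n_components must be in [1, {three_n}]")

    x = sub.reshape(f, three_n)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / f
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|coefficient| entry positive
    for k in range(three_n):
        col = evecs[:, k]
        j = np.argmax(np.abs(col))
        if col[j] < 0:
            evecs[:, k] = -col
    total = evals.sum()
    info = evals / total if total > 0 else np.zeros_like(evals)
    proj = xc @ evecs[:, :n_components]
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        information=info,
        projections=proj,
        mean_structure=mean.reshape(n, 3),
    )


def conformer_density(
    pca_result: PCAResult,
    components: tuple[int, int] = (1, 2),
    bins: int | tuple = 40,
    range_: tuple | None = None,
) -> dict:
    """2-D occupancy histogram of frame scores on two principal components.

    ``components`` are 1-based (PC1, PC2). Returns the normalized histogram
    (sums to 1), bin edges, and an occupied-area estimate: the number of bins
    whose probability mass exceeds 1/F, times the bin area — a simple measure
    of how much conformational space the trajectory visits, comparable
    between runs binned on a common grid.
    """
    proj = pca_result.projections
    f, k = proj.shape
    c1, c2 = components
    if not (1 <= c1 <= k and 1 <= c2 <= k and c1 != c2):
        raise ValueError(f"components {components} out of range for {k} projections")
    x, y = proj[:, c1 - 1], proj[:, c2 - 1]
    hist, xedges, yedges = np.histogram2d(x, y, bins=bins, range=range_)
    density = hist / f
    bin_area = float((xedges[1] - xedges[0]) * (yedges[1] - yedges[0]))
    occupied_bins = int((density > 1.0 / f).sum())
    return {
        "density": density,
        "xedges": xedges,
        "yedges": yedges,
        "occupied_bins": occupied_bins,
        "occupied_area": occupied_bins * bin_area,
    }


def write_correlation_matrix(cm: CorrelationMatrix, path, labels=None) -> None:
    """Whitespace-delimited square matrix with a header line of atom labels."""
    n = cm.matrix.shape[0]
    if labels is None:
        labels = [str(int(i)) for i in cm.selection.indices]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(labels) + "\n")
        for row in cm.matrix:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def write_pca(result: PCAResult, path_eigen, path_proj) -> None:
    """Eigen-system and projection tables as delimited text."""
    with open(path_eigen, "w") as fh:
        fh.write("# component eigenvalue information\n")
        for i, (lam, inf) in enumerate(zip(result.eigenvalues, result.information), 1):
            fh.write(f"{i} {lam:.10g} {inf:.10g}\n")
    with open(path_proj, "w") as fh:
        k = result.projections.shape[1]
        fh.write("# frame " + " ".join(f"PC{i+1}" for i in range(k)) + "\n")
        for f, row in enumerate(result.projections):
            fh.write(f"{f} " + " ".join(f"{v:.10g}" for v in row) + "\n")
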