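"""Anisotropic network model: Hessian construction and normal modes.

The network places a harmonic spring between every pair of nodes closer than
a cutoff r_c at their equilibrium separation.  The potential is

    V = 1/2 * sum_{i<j, s0_ij <= r_c} gamma(s0_ij) * (s_ij - s0_ij)^2

where gamma is either uniform or decays exponentially with the equilibrium
distance.  The 3N x 3N Hessian of V at the equilibrium geometry decomposes
into 6 rigid-body zero modes (for a connected network) plus 3N-6 internal
modes; the pseudo-inverse over internal modes is the model covariance,
the theoretical counterpart of an ensemble's PCA covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .structures import NodeLabel, NodeSet


class DisconnectedNetworkError(ValueError):
    """The contact network falls apart at the chosen cutoff."""


@dataclass(frozen=True)
class ForceConstant:
    """Spring-constant law gamma(r), truncated at the cutoff.

    ``exponential`` reproduces a contact weight of ``gamma0`` at
    ``r_contact`` and decays with ``decay_length``; with the defaults
    (12 at 3 A, decay 4.6 A) the weight has fallen to ~0.1 by 25 A.
    """

    law: str = "exponential"            # "uniform" | "exponential"
    gamma0: float = 12.0                # force constant at contact, arbitrary units
    r_contact: float = 3.0              # Angstrom
    decay_length: float = 4.6           # Angstrom
    cutoff: float = 9.0                 # Angstrom; hard truncation

    def __post_init__(self) -> None:
        if self.law not in ("uniform", "exponential"):
            raise ValueError(f"unknown force-constant law {self.law!r}")
        if self.gamma0 <= 0 or self.decay_length <= 0:
            raise ValueError("gamma0 and decay_length must be positive")
        if self.cutoff <= self.r_contact:
            raise ValueError("cutoff must exceed r_contact")


def gamma_of_r(r: float | np.ndarray, fc: ForceConstant) -> float | np.ndarray:
    """Evaluate the spring constant at separation ``r`` (Angstrom)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    if fc.law == "uniform":
        g = np.full_like(r, fc.gamma0)
    else:
        g = fc.gamma0 * np.exp(-(r - fc.r_contact) / fc.decay_length)
    g = np.where(r <= fc.cutoff, g, 0.0)
    return float(g) if g.ndim == 0 else g


@dataclass
class Hessian:
    values: np.ndarray                   # (3N, 3N) symmetric
    node_labels: list[NodeLabel]
    fc: ForceConstant

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def anm_potential(coords: np.ndarray, reference: np.ndarray, fc: ForceConstant) -> float:
    """Network potential energy of ``coords`` about equilibrium ``reference``.

    Spring constants and connectivity are fixed by the equilibrium geometry,
    so this function is exactly the potential whose second derivatives
    :func:`build_hessian` assembles (the numerical-differentiation oracle
    used in tests relies on that).
    """
    reference = np.asarray(reference, dtype=float)
    coords = np.asarray(coords, dtype=float).reshape(reference.shape)
    s0 = pdist(reference)
    s = pdist(coords)
    g = np.where(s0 <= fc.cutoff, np.asarray(gamma_of_r(s0, fc)), 0.0)
    return float(0.5 * np.sum(g * (s - s0) ** 2))


def build_hessian(nodes: NodeSet, fc: ForceConstant) -> Hessian:
    """Assemble the 3N x 3N ANM Hessian at the node equilibrium geometry.

    The off-diagonal 3x3 super-element of a connected pair (i, j) is
    ``-(gamma_ij / s0_ij^2) d d^T`` with d the equilibrium displacement
    vector; diagonal super-elements make block rows sum to zero
    (translational invariance).
    """
    xyz = nodes.coords
    n = nodes.n_nodes
    if n < 2:
        raise ValueError("need at least two nodes")
    dist = squareform(pdist(xyz))
    connected = (dist <= fc.cutoff) & ~np.eye(n, dtype=bool)
    if not connected.any():
        raise DisconnectedNetworkError(
            f"no node pair within cutoff {fc.cutoff} A; increase the cutoff"
        )
    h = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(connected, k=1))
    for i, j in zip(ii, jj):
        d = xyz[j] - xyz[i]
        s0 = dist[i, j]
        k = gamma_of_r(s0, fc) / s0**2
        block = -k * np.outer(d, d)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return Hessian(h, list(nodes.labels), fc)


# ---------------------------------------------------------------------------
# Modes
# ---------------------------------------------------------------------------

@dataclass
class ModeSet:
    """Eigenvalues and orthonormal eigenvectors of a Hessian or covariance.

    For kind "ANM" eigenvalues ascend (softest first, rigid-body modes
    dropped); for kind "PCA" they are variances in descending order.
    ``mean`` carries the reference coordinates (flattened 3N vector) used by
    projections; it is the ensemble mean for PCA modes.
    """

    eigenvalues: np.ndarray              # (K,)
    eigenvectors: np.ndarray             # (3N, K), columns orthonormal
    kind: str                            # "ANM" | "PCA"
    n_dropped: int
    node_labels: list[NodeLabel]
    mean: np.ndarray | None = None       # (3N,) reference coordinates

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvectors.shape[1] != len(self.eigenvalues):
            raise ValueError("eigenvalue/eigenvector count mismatch")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def vector(self, i: int) -> np.ndarray:
        """Mode vector by 0-based index (0 = softest ANM mode / PC1)."""
        return self.eigenvectors[:, i]


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid translations/rotations about the centroid.

    Shape (3N, r) with r = 6 for a generic geometry (5 for collinear nodes).
    """
    xyz = np.asarray(coords, dtype=float)
    n = len(xyz)
    centred = xyz - xyz.mean(axis=0)
    raw = np.zeros((3 * n, 6))
    for ax in range(3):
        raw[ax::3, ax] = 1.0
    for ax, e in enumerate(np.eye(3)):
        raw[:, 3 + ax] = np.cross(centred, e).ravel()
    q, r = np.linalg.qr(raw)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for k in range(out.shape[1]):
        idx = np.argmax(np.abs(out[:, k]))
        if out[idx, k] < 0:
            out[:, k] = -out[:, k]
    return out


def solve_modes(hessian: Hessian, coords: np.ndarray | None = None,
                zero_tol: float = 1e-8) -> ModeSet:
    """Diagonalize a Hessian, verify and drop its rigid-body null modes.

    Near-zero eigenvalues (|lambda| < zero_tol * lambda_max) must match the
    rank of the analytic rigid-body basis and span it (subspace overlap
    >= 0.99), otherwise the network is disconnected or inconsistent.
    ``coords`` (N x 3) lets the rigid-body check use the true geometry when
    the Hessian was built elsewhere; by default it is reconstructed from the
    labels' node order via the caller passing the NodeSet-derived Hessian.
    """
    h = 0.5 * (hessian.values + hessian.values.T)
    evals, evecs = scipy.linalg.eigh(h)
    lam_max = np.abs(evals).max()
    if lam_max == 0:
        raise DisconnectedNetworkError("Hessian is identically zero")
    near_zero = np.abs(evals) < zero_tol * lam_max
    n_zero = int(near_zero.sum())
    expected = 6
    if coords is not None:
        rigid = rigid_body_basis(coords)
        expected = rigid.shape[1]
        if n_zero > expected:
            raise DisconnectedNetworkError(
                f"{n_zero} near-zero modes (> {expected} rigid-body): "
                "the network has disconnected components"
            )
        zero_vecs = evecs[:, near_zero]
        # average squared projection of each null mode onto the rigid basis
        proj = rigid.T @ zero_vecs
        so = float(np.sqrt(np.sum(proj**2) / max(n_zero, 1)))
        if n_zero and so < 0.99:
            raise ValueError(
                f"rigid-body check failed: null-space overlap {so:.3f} < 0.99"
            )
    elif n_zero > 6:
        raise DisconnectedNetworkError(
            f"{n_zero} near-zero modes (> 6): the network has disconnected components"
        )
    retained = ~near_zero
    mean = None if coords is None else np.asarray(coords, dtype=float).ravel()
    return ModeSet(
        eigenvalues=evals[retained],
        eigenvectors=_fix_signs(evecs[:, retained]),
        kind="ANM",
        n_dropped=n_zero,
        node_labels=list(hessian.node_labels),
        mean=mean,
    )


def anm_modes(nodes: NodeSet, fc: ForceConstant) -> ModeSet:
    """Convenience: Hessian + eigensolution with the rigid-body check."""
    return solve_modes(build_hessian(nodes, fc), coords=nodes.coords)


def anm_covariance(modes: ModeSet) -> np.ndarray:
    """Model covariance sum_i (1/lambda_i) u_i u_i^T (Hessian pseudo-inverse)."""
    if modes.kind != "ANM":
        raise ValueError("anm_covariance expects ANM modes")
    if np.any(modes.eigenvalues <= 0):
        raise ValueError("retained ANM eigenvalues must be positive")
    u = modes.eigenvectors
    return (u / modes.eigenvalues) @ u.T
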