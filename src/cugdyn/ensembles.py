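"""Ensemble PCA, fluctuation profiles, snapshot subsampling and projections.

PCA of an aligned ensemble diagonalizes the covariance of the mean-centred
3N coordinate vectors (divisor m-1).  Applied to trajectory snapshots this
is essential dynamics analysis; applied to superposed crystal fragments it
extracts the experimental deformation modes the elastic network is judged
against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .anm import ModeSet
from .structures import (Ensemble, NodeLabel, NodeSet, align_ensemble,
                         superpose_coords)

logger = logging.getLogger(__name__)


@dataclass
class VarianceSpectrum:
    variances: np.ndarray        # sigma_i, descending (A^2)
    fractions: np.ndarray        # sigma_i / sum, dimensionless
    n_conformers: int

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)


@dataclass
class FluctuationProfile:
    """Per-node RMSF (Angstrom) over an aligned ensemble, for a node subset."""

    values: np.ndarray
    node_labels: list[NodeLabel]
    subset: str                  # "CG" | "P" | "N3" | any atom name

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.node_labels):
            raise ValueError("profile length does not match labels")


def pca_modes(ensemble: Ensemble) -> tuple[ModeSet, VarianceSpectrum]:
    """Principal modes of an aligned ensemble.

    Returns eigenvectors in descending variance order together with the
    variance spectrum; at most min(3N, m-1) components carry variance.
    """
    if not ensemble.aligned:
        raise ValueError("ensemble must be aligned first (align_ensemble)")
    m = ensemble.n_conformers
    if m < 3:
        raise ValueError(f"PCA needs at least 3 conformers, got {m}")
    x = ensemble.coords.reshape(m, -1)
    mean = x.mean(axis=0)
    centred = x - mean
    # economical SVD: right singular vectors are the principal directions
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(x.shape[1], m - 1)
    variances = (svals[:k] ** 2) / (m - 1)
    fractions = variances / variances.sum()
    modes = ModeSet(
        eigenvalues=variances,
        eigenvectors=vt[:k].T,
        kind="PCA",
        n_dropped=0,
        node_labels=list(ensemble.node_labels),
        mean=mean,
    )
    return modes, VarianceSpectrum(variances, fractions, m)


def rmsf(ensemble: Ensemble, subset: str = "CG") -> FluctuationProfile:
    """Root-mean-square fluctuation per node about the ensemble mean.

    ``subset`` is "CG" for every node, or an atom name ("P", "N3", ...) to
    restrict the profile to those beads.
    """
    if not ensemble.aligned:
        raise ValueError("ensemble must be aligned first (align_ensemble)")
    if subset == "CG":
        idx = np.arange(ensemble.n_nodes)
    else:
        idx = np.array(
            [i for i, lab in enumerate(ensemble.node_labels) if lab[3] == subset],
            dtype=int,
        )
    if idx.size == 0:
        raise ValueError(f"subset {subset!r} selects no nodes")
    dev = ensemble.coords[:, idx, :] - ensemble.mean[idx]
    values = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    labels = [ensemble.node_labels[i] for i in idx]
    return FluctuationProfile(values, labels, subset)


def subsample_indices(n_frames: int, n: int) -> np.ndarray:
    """Equally spaced frame indices including the first and last frame."""
    if n == 1:
        return np.array([0])
    return np.round(np.arange(n) * (n_frames - 1) / (n - 1)).astype(int)


def subsample(trajectory: Sequence[NodeSet], n: int = 2000) -> Ensemble:
    """Pick n equally distributed snapshots and align them into an ensemble.

    A trajectory shorter than n is taken whole, with a warning.
    """
    if n < 1:
        raise ValueError("n must be positive")
    m = len(trajectory)
    if m < n:
        logger.warning("trajectory has %d frames < requested %d: taking all", m, n)
        chosen = list(trajectory)
    else:
        chosen = [trajectory[i] for i in subsample_indices(m, n)]
    return align_ensemble(chosen, source=f"subsample({m}->{len(chosen)})")


def project(ensemble: Ensemble, pcs: ModeSet, k: int = 3) -> np.ndarray:
    """Project conformers onto the top-k mode subspace of ``pcs``.

    Each conformer is first rigid-body superposed onto the mode set's
    reference mean (removing rotational/translational contamination of the
    projections), then dotted with the first k eigenvectors.  Row t of the
    returned (m, k) array is conformer t's subspace coordinates.
    """
    if pcs.node_labels != ensemble.node_labels:
        bad = next(
            (p for p in zip(pcs.node_labels, ensemble.node_labels) if p[0] != p[1]),
            (None, None),
        )
        raise ValueError(f"node label mismatch (first: {bad[0]} vs {bad[1]})")
    if pcs.mean is None:
        raise ValueError("mode set carries no reference mean to project against")
    if k < 1 or k > pcs.n_modes:
        raise ValueError(f"k must be in [1, {pcs.n_modes}]")
    mean_xyz = pcs.mean.reshape(-1, 3)
    basis = pcs.eigenvectors[:, :k]
    out = np.empty((ensemble.n_conformers, k))
    for t in range(ensemble.n_conformers):
        moved = superpose_coords(ensemble.coords[t], mean_xyz)
        out[t] = (moved.ravel() - pcs.mean) @ basis
    return out
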