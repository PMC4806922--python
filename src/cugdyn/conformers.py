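"""Conformer generation by deformation along elastic-network modes.

Displacing a reference structure along its softest modes, with amplitudes
drawn as Normal(0, s^2 / lambda_k), produces an ensemble whose covariance is
proportional to the network's own mode covariance — softer modes receive
proportionally larger excursions, as equipartition dictates.  The linear
regime is assumed throughout: no excluded-volume or stereochemistry
filtering is applied to deformed conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anm import ModeSet
from .structures import Ensemble, NodeSet


@dataclass(frozen=True)
class DeformationSpec:
    mode_indices: tuple[int, ...] = (0, 1, 2)   # 0-based, softest first
    n_conformers: int = 2000
    amplitude_rule: str = "gaussian-inverse-lambda"   # | "uniform-grid"
    target_rmsd: float = 2.0                    # Angstrom, rms RMSD from reference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.target_rmsd <= 0:
            raise ValueError("target_rmsd must be positive")
        if self.amplitude_rule not in ("gaussian-inverse-lambda", "uniform-grid"):
            raise ValueError(f"unknown amplitude rule {self.amplitude_rule!r}")


def deform_along_mode(reference: NodeSet, mode: np.ndarray, amplitude: float) -> NodeSet:
    """Displace a structure by ``amplitude`` along a unit mode vector.

    The resulting RMSD from the reference is exactly |amplitude| / sqrt(N).
    """
    mode = np.asarray(mode, dtype=float).ravel()
    if mode.shape != (3 * reference.n_nodes,):
        raise ValueError(
            f"mode length {mode.shape[0]} does not match {reference.n_nodes} nodes"
        )
    return reference.with_coords(reference.coords + amplitude * mode.reshape(-1, 3))


def _amplitude_scale(eigenvalues: np.ndarray, n_nodes: int, target_rmsd: float) -> float:
    # E[RMSD^2] = sum_k s^2/lambda_k / N  ==>  s for rms RMSD = target
    return math.sqrt(target_rmsd**2 * n_nodes / np.sum(1.0 / eigenvalues))


def sample_conformers(reference: NodeSet, modes: ModeSet,
                      spec: DeformationSpec = DeformationSpec()) -> Ensemble:
    """Generate an ensemble by deforming along selected ANM modes.

    gaussian-inverse-lambda: amplitudes c_k ~ Normal(0, s^2 / lambda_k) with
    the global scale s set so the root-mean-square RMSD from the reference
    equals ``spec.target_rmsd``.  uniform-grid: a deterministic grid over
    [-a_k, a_k] per mode with matching per-mode variance.  Pure mode
    displacements add no rigid motion, so the ensemble is already aligned.
    """
    if modes.kind != "ANM":
        raise ValueError("sample_conformers expects ANM modes")
    if modes.node_labels != reference.labels:
        raise ValueError("mode set and reference carry different node labels")
    idx = np.asarray(spec.mode_indices, dtype=int)
    if np.any(idx < 0) or np.any(idx >= modes.n_modes):
        raise ValueError(f"mode indices out of range [0, {modes.n_modes})")
    lam = modes.eigenvalues[idx]
    if np.any(lam <= 0):
        raise ValueError("selected modes must have positive eigenvalues")
    basis = modes.eigenvectors[:, idx]                    # (3N, k)
    s = _amplitude_scale(lam, reference.n_nodes, spec.target_rmsd)
    k = len(idx)
    if spec.amplitude_rule == "gaussian-inverse-lambda":
        rng = np.random.default_rng(spec.seed)
        amplitudes = rng.standard_normal((spec.n_conformers, k)) * (s / np.sqrt(lam))
    else:
        per_axis = max(2, math.ceil(spec.n_conformers ** (1.0 / k)))
        a = s * np.sqrt(3.0 / lam)                        # uniform on [-a, a]: var a^2/3
        grids = np.meshgrid(*[np.linspace(-ai, ai, per_axis) for ai in a],
                            indexing="ij")
        amplitudes = np.stack([g.ravel() for g in grids], axis=1)[: spec.n_conformers]
    coords = reference.coords.ravel() + amplitudes @ basis.T
    return Ensemble(
        coords.reshape(spec.n_conformers if len(amplitudes) == spec.n_conformers
                       else len(amplitudes), -1, 3),
        list(reference.labels),
        aligned=True,
        source=f"anm-deform(k={k}, rule={spec.amplitude_rule}, seed={spec.seed})",
    )
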