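"""Mode- and fluctuation-comparison metrics, and the parameter scan.

All comparisons use absolute overlaps because eigenvector signs are
arbitrary.  Mode indices in reports are 1-based after rigid-body removal
("ANM2" is the second-softest retained network mode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .anm import DisconnectedNetworkError, ForceConstant, ModeSet, anm_modes
from .ensembles import FluctuationProfile, pca_modes, project
from .structures import (Ensemble, RnaStructure, align_ensemble,
                         common_node_subset, get_scheme, positional_nodes,
                         select_nodes)

logger = logging.getLogger(__name__)


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"{name}: zero vector")
    if abs(norm - 1.0) > 1e-6:
        warnings.warn(f"{name}: renormalizing (|v| = {norm:.6g})", stacklevel=3)
        v = v / norm
    return v


def overlap(p: np.ndarray, u: np.ndarray) -> float:
    """|p . u| of two unit mode vectors; 1 means identical directions."""
    p = _unit(p, "p")
    u = _unit(u, "u")
    if p.shape != u.shape:
        raise ValueError(f"mode length mismatch: {p.shape} vs {u.shape}")
    return float(abs(p @ u))


def overlap_matrix(set_a: ModeSet, set_b: ModeSet,
                   k_a: int | None = None, k_b: int | None = None) -> np.ndarray:
    """|O_ij| between the first k_a modes of A (rows) and k_b of B (columns)."""
    k_a = set_a.n_modes if k_a is None else k_a
    k_b = set_b.n_modes if k_b is None else k_b
    return np.abs(set_a.eigenvectors[:, :k_a].T @ set_b.eigenvectors[:, :k_b])


def cumulative_overlap(pc: np.ndarray, modes: ModeSet, j: int) -> float:
    """How well the j softest modes of a set span one target mode.

    CO = sqrt(sum_{i<=j} O_i^2); reaches 1 when the set is complete.
    """
    if j < 1:
        raise ValueError("J must be >= 1")
    if j > modes.n_modes:
        raise ValueError(f"J = {j} exceeds the {modes.n_modes} available modes")
    pc = _unit(pc, "pc")
    dots = pc @ modes.eigenvectors[:, :j]
    return float(np.sqrt(np.sum(dots**2)))


def subspace_overlap(set_a: ModeSet, set_b: ModeSet, k: int) -> float:
    """Root-mean agreement of the two top-K essential subspaces.

    SO_K = sqrt(1/K * sum_{i,j<=K} O_ij^2); 1 for identical subspaces,
    0 for orthogonal ones; symmetric in its arguments.
    """
    if k < 1 or k > min(set_a.n_modes, set_b.n_modes):
        raise ValueError(f"K must be in [1, {min(set_a.n_modes, set_b.n_modes)}]")
    if set_a.node_labels != set_b.node_labels:
        raise ValueError("mode sets share no common node labelling")
    o = overlap_matrix(set_a, set_b, k, k)
    return float(np.sqrt(np.sum(o**2) / k))


def collectivity(u: np.ndarray, n_nodes: int) -> float:
    """Brueschweiler degree of collectivity of a mode, in [1/N, 1].

    Per-node squared displacements (summed over x, y, z) are normalized to a
    distribution whose exponential entropy, divided by N, measures how many
    nodes the mode moves: 1/N for a single-node mode, 1 for a uniform one.
    """
    u = np.asarray(u, dtype=float).ravel()
    if len(u) != 3 * n_nodes:
        raise ValueError(f"mode length {len(u)} != 3 * {n_nodes}")
    m = np.sum(u.reshape(n_nodes, 3) ** 2, axis=1)
    total = m.sum()
    if total == 0:
        raise ValueError("zero mode vector")
    m = m / total
    nz = m[m > 0]
    entropy = -float(np.sum(nz * np.log(nz)))     # 0 * log 0 := 0
    return float(np.exp(entropy) / n_nodes)


def fluctuation_correlation(a: FluctuationProfile, b: FluctuationProfile) -> float:
    """Pearson correlation of two RMSF profiles over the same node subset."""
    if a.subset != b.subset:
        raise ValueError(f"subset mismatch: {a.subset} vs {b.subset}")
    if a.node_labels != b.node_labels:
        raise ValueError("profiles cover different nodes")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    return float(pearsonr(a.values, b.values).statistic)


def projection_correlation(ensemble: Ensemble, pcs: ModeSet, mode_a: int,
                           other: ModeSet, mode_b: int) -> float:
    """|Pearson r| between conformer projections onto two mode vectors.

    Measures how tightly the ensemble's scatter along one mode (e.g. PC1)
    tracks its scatter along another (e.g. the second-softest ANM mode).
    Both projections use the first mode set's reference frame.
    """
    series_a = project(ensemble, pcs, k=mode_a + 1)[:, mode_a]
    ref = replace_mean(other, pcs.mean)
    series_b = project(ensemble, ref, k=mode_b + 1)[:, mode_b]
    return float(abs(pearsonr(series_a, series_b).statistic))


def replace_mean(modes: ModeSet, mean: np.ndarray | None) -> ModeSet:
    return ModeSet(modes.eigenvalues, modes.eigenvectors, modes.kind,
                   modes.n_dropped, list(modes.node_labels), mean)


# ---------------------------------------------------------------------------
# Cutoff / scheme scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Grid of best |overlap(softest ANM modes, PC1)| per model parameters."""

    table: pd.DataFrame          # scheme, cutoff, law, best_overlap, best_mode, failed
    n_soft: int

    @property
    def best(self) -> pd.Series:
        ok = self.table[~self.table.failed]
        if ok.empty:
            raise DisconnectedNetworkError("every scan cell failed")
        # ties break toward the smaller cutoff (sparser model)
        ranked = ok.sort_values(["best_overlap", "cutoff"],
                                ascending=[False, True], kind="stable")
        return ranked.iloc[0]


def scan_parameters(
    reference: RnaStructure,
    conformers: Sequence[RnaStructure] | None = None,
    schemes: Sequence[str] = ("ALL", "CG1", "CG2"),
    cutoffs: Sequence[float] = tuple(range(5, 16)),
    fc_laws: Sequence[str] = ("exponential",),
    fc_template: ForceConstant = ForceConstant(),
    n_soft: int = 6,
    pcs: ModeSet | None = None,
) -> ScanResult:
    """Scan coarse-grain scheme, cutoff and force-constant law.

    For each scheme the conformers are coarse-grained, aligned and reduced
    to their first principal component; each (cutoff, law) cell builds an
    ANM on the equally coarse-grained reference and records the best
    |overlap| any of the ``n_soft`` softest modes achieves with PC1.
    Disconnected cells are marked failed and the scan continues.

    ``pcs`` supplies precomputed principal modes instead of ``conformers``;
    their node labelling pins the coarse-graining, so exactly one scheme
    may then be scanned.
    """
    if (conformers is None) == (pcs is None):
        raise ValueError("supply exactly one of conformers or pcs")
    if pcs is not None and len(schemes) != 1:
        raise ValueError("precomputed pcs pin the scheme: scan exactly one")
    rows = []
    for scheme_name in schemes:
        scheme = get_scheme(scheme_name)
        if pcs is None:
            # positional labels + common subset: conformers and reference may
            # disagree on terminal phosphates and author numbering
            all_nodes = [positional_nodes(select_nodes(s, scheme))
                         for s in (*conformers, reference)]
            *conf_nodes, ref_nodes = common_node_subset(all_nodes)
            ens = align_ensemble(conf_nodes, source=f"scan:{scheme.name}")
            scheme_pcs, _ = pca_modes(ens)
        else:
            # correspondence with precomputed pcs is by node order
            scheme_pcs = pcs
            ref_nodes = select_nodes(reference, scheme)
        pc1 = scheme_pcs.vector(0)
        if ref_nodes.n_nodes != scheme_pcs.n_nodes:
            raise ValueError(
                f"scheme {scheme.name}: reference has {ref_nodes.n_nodes} nodes "
                f"but the ensemble modes cover {scheme_pcs.n_nodes}"
            )
        for law in fc_laws:
            for cutoff in cutoffs:
                fc = replace(fc_template, law=law, cutoff=float(cutoff))
                try:
                    modes = anm_modes(ref_nodes, fc)
                except (DisconnectedNetworkError, ValueError) as exc:
                    logger.info("scan cell (%s, %g, %s) failed: %s",
                                scheme.name, cutoff, law, exc)
                    rows.append(dict(scheme=scheme.name, cutoff=float(cutoff),
                                     law=law, best_overlap=np.nan, best_mode=0,
                                     failed=True))
                    continue
                k = min(n_soft, modes.n_modes)
                ovl = np.abs(pc1 @ modes.eigenvectors[:, :k])
                best = int(np.argmax(ovl))
                rows.append(dict(scheme=scheme.name, cutoff=float(cutoff), law=law,
                                 best_overlap=float(ovl[best]),
                                 best_mode=best + 1, failed=False))
    return ScanResult(pd.DataFrame(rows), n_soft)
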