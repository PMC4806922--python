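"""Non-canonical U-U pair location, geometry, classification and clustering.

U-U pairs in CUG-repeat helices are 1x1 internal loops flanked by canonical
C-G/G-C pairs.  Crystallography and MD group their conformations into six
types by hydrogen-bond count (0, 1 or 2) and inclination toward the major
or minor groove:

    type  I   2 bonds, minor        type IV   1 bond,  major
    type  II  1 bond,  minor        type V    2 bonds, major
    type  III 0 bonds, not inclined type VI   0 bonds, major

Hydrogen bonds are detected on heavy atoms (donor N3, acceptors O2/O4 of
the partner) with a distance cutoff, plus a donor-H...acceptor angle test
when hydrogens are present.  Inclination is measured as the displacement of
the uracil base centroids along a calibrated groove axis, relative to the
same quantity on the ideal builder geometry, with a +-0.5 A dead zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .structures import (Residue, RnaStructure, WC_PAIRS, kabsch_superpose,
                         pair_chains)

#: (n_hbonds, inclination) -> type label
TYPE_TABLE = {
    (2, "minor"): "I",
    (1, "minor"): "II",
    (0, "none"): "III",
    (1, "major"): "IV",
    (2, "major"): "V",
    (0, "major"): "VI",
}
TYPE_REQUIREMENTS = {v: k for k, v in TYPE_TABLE.items()}

_UU_HEAVY = ("C1'", "C2'", "C4'", "N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6")
_FLANK_FIT = ("C1'", "N1", "C2", "N3", "C4", "C5", "C6")   # + purine ring below

INCLINATION_DEAD_ZONE = 0.5   # Angstrom


@dataclass
class UUPair:
    res_a: Residue                  # reference-strand uracil
    res_b: Residue                  # partner-strand uracil
    position: tuple[int, int]       # chain-local positions (i, j)
    flank_5: tuple[Residue, Residue]
    flank_3: tuple[Residue, Residue]

    @property
    def label(self) -> str:
        return (f"{self.res_a.chain_id}{self.res_a.index}-"
                f"{self.res_b.chain_id}{self.res_b.index}")


@dataclass
class HBond:
    donor: str                      # e.g. "A5:N3"
    acceptor: str
    distance: float                 # Angstrom
    angle: float | None = None      # degrees, absent without hydrogens


@dataclass
class UUClass:
    type_label: str                 # I..VI
    n_hbonds: int
    inclination: str                # minor | none | major
    displacement: float             # Angstrom along the groove axis
    c1c1_distance: float            # Angstrom
    atypical: bool = False


def find_uu_pairs(structure: RnaStructure) -> list[UUPair]:
    """Locate U-U pairs at complementary duplex positions with canonical flanks.

    Returns an empty list for a pure Watson-Crick duplex; raises only if the
    structure is not a duplex at all.
    """
    pairing = pair_chains(structure)
    pair_map = dict(pairing.pairs)
    ra, rb = pairing.chain_a.residues, pairing.chain_b.residues
    out: list[UUPair] = []
    for i, j in pairing.pairs:
        if ra[i].name != "U" or rb[j].name != "U":
            continue
        jm, jp = pair_map.get(i - 1), pair_map.get(i + 1)
        if jm is None or jp is None:
            continue
        if jm != j + 1 or jp != j - 1:
            continue
        if (ra[i - 1].name, rb[jm].name) not in WC_PAIRS:
            continue
        if (ra[i + 1].name, rb[jp].name) not in WC_PAIRS:
            continue
        out.append(
            UUPair(
                res_a=ra[i],
                res_b=rb[j],
                position=(i, j),
                flank_5=(ra[i - 1], rb[jm]),
                flank_3=(ra[i + 1], rb[jp]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds and distances
# ---------------------------------------------------------------------------

def detect_hbonds(pair: UUPair, dist_cutoff: float = 3.5,
                  angle_cutoff: float = 135.0) -> list[HBond]:
    """Direct hydrogen bonds of a U-U pair (0, 1 or 2).

    Candidates are N3(a)->O2/O4(b) and N3(b)->O2/O4(a); a candidate passes
    on heavy-atom distance, and additionally on the N3-H...O angle when an
    imino hydrogen (H3) is present.  Each donor contributes at most one
    bond (closest acceptor wins).
    """
    for res in (pair.res_a, pair.res_b):
        for name in ("N3", "O2", "O4"):
            if res.atom(name) is None:
                raise ValueError(
                    f"residue {res.chain_id}{res.index}: missing atom {name}"
                )
    bonds: list[HBond] = []
    for donor_res, acc_res in ((pair.res_a, pair.res_b), (pair.res_b, pair.res_a)):
        n3 = donor_res.atom("N3")
        candidates = []
        for acc_name in ("O2", "O4"):
            acc = acc_res.atom(acc_name)
            d = float(np.linalg.norm(n3.coords - acc.coords))
            if d > dist_cutoff:
                continue
            angle = None
            h3 = donor_res.atom("H3")
            if h3 is not None:
                v1 = n3.coords - h3.coords
                v2 = acc.coords - h3.coords
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle < angle_cutoff:
                    continue
            candidates.append((d, acc_name, angle))
        if candidates:
            d, acc_name, angle = min(candidates)
            bonds.append(
                HBond(
                    donor=f"{donor_res.chain_id}{donor_res.index}:N3",
                    acceptor=f"{acc_res.chain_id}{acc_res.index}:{acc_name}",
                    distance=d,
                    angle=angle,
                )
            )
    return bonds[:2]


def c1c1_distance(pair: UUPair) -> float:
    """C1'-C1' distance of the pair (Angstrom); ~10.4 for Watson-Crick geometry."""
    a = pair.res_a.atom("C1'")
    b = pair.res_b.atom("C1'")
    if a is None or b is None:
        raise ValueError(f"pair {pair.label}: missing C1' atom")
    return float(np.linalg.norm(a.coords - b.coords))


# ---------------------------------------------------------------------------
# Inclination
# ---------------------------------------------------------------------------

def _c1_midpoint(res_pair: tuple[Residue, Residue]) -> np.ndarray:
    pts = []
    for res in res_pair:
        a = res.atom("C1'")
        if a is None:
            raise ValueError(f"residue {res.chain_id}{res.index}: missing C1'")
        pts.append(a.coords)
    return 0.5 * (pts[0] + pts[1])


def groove_axis(pair: UUPair) -> np.ndarray:
    """Calibrated groove axis g of a U-U pair.

    g = h x l with h the local helix axis (between the flanking pairs'
    C1'-C1' midpoints) and l the pair long axis; the sign is fixed so the
    flanking canonical pairs' base centroids project negative.
    """
    h = _c1_midpoint(pair.flank_3) - _c1_midpoint(pair.flank_5)
    h = h / np.linalg.norm(h)
    l = pair.res_b.atom("C1'").coords - pair.res_a.atom("C1'").coords
    l = l / np.linalg.norm(l)
    g = np.cross(h, l)
    norm = np.linalg.norm(g)
    if norm < 1e-8:
        raise ValueError(f"pair {pair.label}: degenerate helix/long axes")
    g = g / norm
    proj = 0.0
    for flank in (pair.flank_5, pair.flank_3):
        mid = _c1_midpoint(flank)
        centroid = 0.5 * (flank[0].base_centroid() + flank[1].base_centroid())
        proj += (centroid - mid) @ g
    if proj > 0:
        g = -g
    return g


def _raw_displacement(pair: UUPair) -> tuple[float, np.ndarray]:
    g = groove_axis(pair)
    mid = _c1_midpoint((pair.res_a, pair.res_b))
    centroid = 0.5 * (pair.res_a.base_centroid() + pair.res_b.base_centroid())
    return float((centroid - mid) @ g), g


_IDEAL_RAW: float | None = None


def _ideal_raw() -> float:
    """Raw groove displacement of the unperturbed builder U-U (the zero point)."""
    global _IDEAL_RAW
    if _IDEAL_RAW is None:
        from .synthetic import build_cug_duplex

        ideal = build_cug_duplex(2, cap="GC")
        raw, _ = _raw_displacement(find_uu_pairs(ideal)[0])
        _IDEAL_RAW = raw
    return _IDEAL_RAW


def groove_displacement(pair: UUPair) -> tuple[float, np.ndarray]:
    """(displacement relative to the ideal reference, groove axis g)."""
    raw, g = _raw_displacement(pair)
    return raw - _ideal_raw(), g


def inclination(pair: UUPair) -> tuple[str, float]:
    """Groove-inclination label and displacement (Angstrom).

    major if displacement > +0.5 A, minor if < -0.5 A, else none.  Terminal
    U-U pairs (no flanking canonical pair) never reach here: find_uu_pairs
    only returns flanked pairs.
    """
    disp, _ = groove_displacement(pair)
    if disp > INCLINATION_DEAD_ZONE:
        return "major", disp
    if disp < -INCLINATION_DEAD_ZONE:
        return "minor", disp
    return "none", disp


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_uu(pair: UUPair, dist_cutoff: float = 3.5,
                angle_cutoff: float = 135.0) -> UUClass:
    """Assign a U-U pair to type I-VI by hydrogen bonds and inclination.

    Combinations outside the six-type table — (2, none), (1, none) and
    (0, minor) — are mapped to the nearest type for that bond count (the
    displacement sign breaks the tie) and flagged atypical.
    """
    n_hb = len(detect_hbonds(pair, dist_cutoff, angle_cutoff))
    label, disp = inclination(pair)
    key = (n_hb, label)
    if key in TYPE_TABLE:
        return UUClass(TYPE_TABLE[key], n_hb, label, disp, c1c1_distance(pair))
    if n_hb == 0:
        coerced = "none" if label == "minor" else "major"
    else:
        coerced = "major" if disp >= 0 else "minor"
    return UUClass(TYPE_TABLE[(n_hb, coerced)], n_hb, label, disp,
                   c1c1_distance(pair), atypical=True)


# ---------------------------------------------------------------------------
# Conformation clustering across trajectory frames
# ---------------------------------------------------------------------------

@dataclass
class UUClusterResult:
    labels: np.ndarray              # (m,) cluster id per frame, 1-based by population
    populations: np.ndarray         # fraction per cluster, descending
    centroid_frames: list[int]      # representative frame per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def _pair_atoms(frame: RnaStructure, pair_index: int, frame_no: int):
    pairs = find_uu_pairs(frame)
    if pair_index >= len(pairs):
        raise ValueError(
            f"frame {frame_no}: U-U pair {pair_index} absent "
            f"({len(pairs)} pairs found)"
        )
    pair = pairs[pair_index]
    uu = np.vstack([res.coords_of([a for a in _UU_HEAVY if res.atom(a) is not None])
                    for res in (pair.res_a, pair.res_b)])
    flank = []
    for fp in (pair.flank_5, pair.flank_3):
        for res in fp:
            names = ["C1'"] + [a for a in res.ring_atom_names()
                               if res.atom(a) is not None]
            flank.append(res.coords_of(names))
    return uu, np.vstack(flank)


def uu_pairwise_rmsd(frames: Sequence[RnaStructure], pair_index: int) -> np.ndarray:
    """Pairwise internal RMSD (A) of one U-U pair across frames.

    Frames are superposed on the flanking canonical pairs before measuring
    the RMSD over the uracils' heavy atoms, so internal pair motion rather
    than global drift drives the distances.
    """
    geoms = [_pair_atoms(f, pair_index, t) for t, f in enumerate(frames)]
    m = len(geoms)
    if any(g[0].shape != geoms[0][0].shape or g[1].shape != geoms[0][1].shape
           for g in geoms):
        raise ValueError("inconsistent atom sets across frames")
    dist = np.zeros((m, m))
    for i in range(m):
        uu_i, flank_i = geoms[i]
        for j in range(i + 1, m):
            uu_j, flank_j = geoms[j]
            rot, trans, _ = kabsch_superpose(flank_j, flank_i)
            moved = uu_j @ rot.T + trans
            dist[i, j] = dist[j, i] = float(
                np.sqrt(np.mean(np.sum((moved - uu_i) ** 2, axis=1)))
            )
    return dist


def cluster_uu_trajectory(frames: Sequence[RnaStructure], pair_index: int = 0,
                          threshold: float = 3.0) -> UUClusterResult:
    """Average-linkage clustering of one U-U pair's conformations.

    Merging stops when the smallest inter-cluster average distance exceeds
    ``threshold`` (Angstrom).  Clusters are numbered by population (1 =
    largest); populations sum to 1; each cluster reports the frame closest
    on average to its members.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    dist = uu_pairwise_rmsd(frames, pair_index)
    m = len(frames)
    if np.allclose(dist, 0):
        raw = np.ones(m, dtype=int)
    else:
        linkage = sch.linkage(squareform(dist, checks=False), method="average")
        raw = sch.fcluster(linkage, t=threshold, criterion="distance")
    ids, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    relabel = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    populations = counts[order] / m
    centroids = []
    for rank in range(1, len(ids) + 1):
        members = np.nonzero(labels == rank)[0]
        mean_d = dist[np.ix_(members, members)].mean(axis=1)
        centroids.append(int(members[np.argmin(mean_d)]))
    return UUClusterResult(labels, populations, centroids)
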