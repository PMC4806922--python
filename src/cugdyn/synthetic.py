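"""Synthetic inputs: idealized A-form CUG duplexes and Gaussian ensembles.

The duplex builder places a reduced, deliberately *non-chemical* atom
dictionary — backbone probes P/C1'/C2'/C4' plus full planar base rings with
the exocyclic O2/O4/N4/O6/N2/N6 — sufficient for every coarse-graining
scheme and for U-U pair typing, but not a thermodynamically meaningful
model.  Base rings are regular polygons (bond length 1.38 A); base-pair
geometry (hydrogen-bond distances, glycosidic orientations) is solved
numerically per pair type so that canonical pairs meet Watson-Crick
distance checks and U-U pairs adopt the stretched-wobble geometry (one
N3...O4 contact) by default.  Pairs stack under the standard A-form helical
transform (twist/rise/x-displacement/inclination).

Gaussian ensembles with prescribed low-rank mode structure stand in for
crystal-fragment ensembles and MD snapshot sets, giving every downstream
analysis a generative ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .structures import (Atom, Chain, Ensemble, NodeSet, Residue,
                         RnaStructure, write_node_pdb)

_LAMBDA = math.radians(54.5)      # glycosidic bond angle to the C1'-C1' line
_C1_HALF = 5.2                    # half the Watson-Crick C1'-C1' distance, A
_GLYC_LEN = 1.48                  # C1'-N glycosidic bond length, A
_RING_BOND = 1.38                 # ring bond length, A
_HBOND = 2.9                      # donor-acceptor distance built into pairs, A
_APART = 4.6                      # "no hydrogen bond" donor-acceptor distance, A

COMPLEMENT = {"A": "U", "U": "U", "G": "C", "C": "G"}   # U pairs U in CUG duplexes

# backbone probe offsets relative to C1', left (strand A) side of the pair frame
_BACKBONE_OFFSETS = {
    "C2'": np.array([-0.9, -1.1, 0.7]),
    "C4'": np.array([-2.0, -0.3, 1.3]),
    "P": np.array([-2.6, 1.4, -1.45]),
}

_PYRIMIDINE_EDGE = {"U": ("O2", "N3", "O4"), "C": ("O2", "N3", "N4")}
_PURINE_EDGE = {"G": ("O6", "N1", "N2"), "A": ("N6", "N1", "C2")}


@dataclass(frozen=True)
class HelixParams:
    """A-form helical step parameters (fiber-diffraction canon).

    ``x_displacement`` shifts each pair along its groove axis away from the
    helix axis, carving the deep A-form major groove; ``inclination`` tilts
    the pair plane off the perpendicular to the axis.
    """

    twist: float = 32.7           # degrees per step
    rise: float = 2.81            # Angstrom per step
    x_displacement: float = -4.4  # Angstrom
    inclination: float = 19.0     # degrees

    def __post_init__(self) -> None:
        if not (0 < self.twist < 360):
            raise ValueError("twist must be in (0, 360) degrees")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


# ---------------------------------------------------------------------------
# Planar base templates (local frame: glycosidic N at the origin)
# ---------------------------------------------------------------------------

def _polar(radius: float, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return radius * np.array([math.cos(a), math.sin(a)])


@lru_cache(maxsize=None)
def _base_local(base: str) -> dict:
    """2-D atom positions of a base, glycosidic nitrogen at the origin."""
    atoms: dict[str, np.ndarray] = {}
    if base in ("U", "C"):
        center = np.array([_RING_BOND, 0.0])
        ring = ("N1", "C2", "N3", "C4", "C5", "C6")
        for k, name in enumerate(ring):
            atoms[name] = center + _polar(_RING_BOND, 180.0 - 60.0 * k)
        atoms["O2"] = atoms["C2"] + 1.23 * _unit2(atoms["C2"] - center)
        if base == "U":
            atoms["O4"] = atoms["C4"] + 1.23 * _unit2(atoms["C4"] - center)
        else:
            atoms["N4"] = atoms["C4"] + 1.34 * _unit2(atoms["C4"] - center)
    elif base in ("A", "G"):
        p5 = np.array([2.0 * _RING_BOND * math.sin(math.radians(54)) / 2
                       / math.sin(math.radians(36)) * math.sin(math.radians(36)), 0.0])
        # pentagon circumradius for side _RING_BOND
        r5 = _RING_BOND / (2.0 * math.sin(math.radians(36)))
        p5 = np.array([r5, 0.0])
        five = ("N9", "C8", "N7", "C5", "C4")
        for k, name in enumerate(five):
            atoms[name] = p5 + _polar(r5, 180.0 - 72.0 * k)
        # hexagon fused along C4-C5
        mid = 0.5 * (atoms["C4"] + atoms["C5"])
        edge = atoms["C5"] - atoms["C4"]
        normal = np.array([edge[1], -edge[0]]) / np.linalg.norm(edge)
        if np.dot(mid + normal - p5, mid - p5) < np.dot(mid - normal - p5, mid - p5):
            normal = -normal
        h = mid + (_RING_BOND * math.sqrt(3.0) / 2.0) * normal
        theta0 = math.degrees(math.atan2(*(atoms["C4"] - h)[::-1]))
        for k, name in enumerate(("C4", "C5", "C6", "N1", "C2", "N3")):
            atoms[name] = h + _polar(_RING_BOND, theta0 - 60.0 * k)
        if base == "G":
            atoms["O6"] = atoms["C6"] + 1.23 * _unit2(atoms["C6"] - h)
            atoms["N2"] = atoms["C2"] + 1.34 * _unit2(atoms["C2"] - h)
        else:
            atoms["N6"] = atoms["C6"] + 1.34 * _unit2(atoms["C6"] - h)
    else:
        raise ValueError(f"invalid base {base!r}")
    return atoms


def _unit2(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rot2(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def _glyc_left() -> np.ndarray:
    return np.array([-_C1_HALF, 0.0]) + _GLYC_LEN * np.array(
        [math.cos(_LAMBDA), math.sin(_LAMBDA)]
    )


def _place_left(base: str, angle: float) -> dict:
    """Place a base on the left (-x) side of the pair frame, rotated in-plane."""
    glyc = _glyc_left()
    rot = _rot2(angle)
    out = {name: glyc + rot @ p for name, p in _base_local(base).items()}
    out["C1'"] = np.array([-_C1_HALF, 0.0])
    return out


def _mirror_x(atoms: dict) -> dict:
    return {name: np.array([-p[0], p[1]]) for name, p in atoms.items()}


_PAIR_CONSTRAINTS = {
    ("G", "C"): [("L", "N1", "R", "N3", _HBOND), ("L", "O6", "R", "N4", _HBOND)],
    ("C", "G"): [("L", "N3", "R", "N1", _HBOND), ("L", "N4", "R", "O6", _HBOND)],
    ("A", "U"): [("L", "N1", "R", "N3", _HBOND), ("L", "N6", "R", "O4", _HBOND)],
    ("U", "A"): [("L", "N3", "R", "N1", _HBOND), ("L", "O4", "R", "N6", _HBOND)],
}

_UU_VARIANTS = {
    # hydrogen-bond count -> donor/acceptor distance targets
    1: [("L", "O4", "R", "N3", _HBOND), ("L", "N3", "R", "O4", _APART)],   # stretched wobble
    2: [("L", "O4", "R", "N3", _HBOND), ("L", "N3", "R", "O4", _HBOND)],   # symmetric
    0: [("L", "O4", "R", "N3", _APART), ("L", "N3", "R", "O4", _APART)],   # open
}


def _edge_atoms(base: str) -> tuple[str, ...]:
    return _PYRIMIDINE_EDGE.get(base) or _PURINE_EDGE[base]


def _initial_angle(base: str) -> float:
    """Start the orientation solve with the pairing edge aimed at the partner."""
    local = _base_local(base)
    edge = np.mean([local[a] for a in _edge_atoms(base)], axis=0)
    glyc = _glyc_left()
    target = np.array([-glyc[0], glyc[1]])        # the partner's glycosidic N
    desired = math.atan2(*(target - glyc)[::-1])
    current = math.atan2(*edge[::-1])
    return desired - current


@lru_cache(maxsize=None)
def _pair_template(base_left: str, base_right: str, variant: int = -1) -> tuple:
    """Solve the in-plane orientation of a base pair in the pair frame.

    ``variant`` selects the U-U hydrogen-bond count (0/1/2); -1 means the
    canonical Watson-Crick constraint set.  Returns two dicts (left, right)
    of 2-D coordinates.
    """
    if variant >= 0:
        constraints = _UU_VARIANTS[variant]
    else:
        constraints = _PAIR_CONSTRAINTS[(base_left, base_right)]

    def build(theta):
        left = _place_left(base_left, theta[0])
        right = _mirror_x(_place_left(base_right, theta[1]))
        return left, right

    def residuals(theta):
        left, right = build(theta)
        out = []
        for side_a, atom_a, side_b, atom_b, target in constraints:
            pa = left[atom_a] if side_a == "L" else right[atom_a]
            pb = right[atom_b] if side_b == "R" else left[atom_b]
            out.append(np.linalg.norm(pa - pb) - target)
        return out

    x0 = np.array([_initial_angle(base_left), _initial_angle(base_right)])
    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    if np.max(np.abs(sol.fun)) > 0.05:
        raise ValueError(
            f"pair geometry {base_left}-{base_right} (variant {variant}) "
            f"unsolvable: residual {np.max(np.abs(sol.fun)):.2f} A"
        )
    left, right = build(sol.x)
    return (
        {k: tuple(v) for k, v in left.items()},
        {k: tuple(v) for k, v in right.items()},
    )


def uu_pair_template(n_hbonds: int) -> tuple[dict, dict]:
    """U-U pair-frame geometry with the requested hydrogen-bond count."""
    if n_hbonds not in (0, 1, 2):
        raise ValueError("n_hbonds must be 0, 1 or 2")
    left, right = _pair_template("U", "U", n_hbonds)
    return (
        {k: np.array(v) for k, v in left.items()},
        {k: np.array(v) for k, v in right.items()},
    )


# ---------------------------------------------------------------------------
# Duplex assembly
# ---------------------------------------------------------------------------

_BASE_ATOM_ORDER = {
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N2", "N1", "C6", "O6"),
    "A": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"),
}


def _step_transform(k: int, params: HelixParams):
    incl = math.radians(params.inclination)
    tw = math.radians(params.twist) * k
    rx = np.array([[1, 0, 0],
                   [0, math.cos(incl), -math.sin(incl)],
                   [0, math.sin(incl), math.cos(incl)]])
    rz = np.array([[math.cos(tw), -math.sin(tw), 0],
                   [math.sin(tw), math.cos(tw), 0],
                   [0, 0, 1]])

    def apply(p: np.ndarray) -> np.ndarray:
        q = rx @ p
        q = q + np.array([0.0, params.x_displacement, 0.0])
        q = rz @ q
        return q + np.array([0.0, 0.0, params.rise * k])

    return apply


def build_aform_duplex(
    sequence: str,
    params: HelixParams = HelixParams(),
    chain_ids: tuple[str, str] = ("A", "B"),
) -> RnaStructure:
    """Build an idealized A-form duplex for ``sequence`` (strand A, 5'->3').

    The complementary strand is derived with U paired to U, so CUG-repeat
    sequences form the canonical G-C / U-U / C-G repeat motif.  U-U pairs
    adopt the stretched-wobble (single N3...O4 hydrogen bond) geometry.
    5'-terminal residues carry no phosphate.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGU")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    n = len(sequence)
    res_a: list[Residue] = []
    res_b: list[Residue] = []
    serial = 0
    for k, base_a in enumerate(sequence):
        base_b = COMPLEMENT[base_a]
        if (base_a, base_b) == ("U", "U"):
            left2d, right2d = _pair_template("U", "U", 1)
        else:
            left2d, right2d = _pair_template(base_a, base_b)
        transform = _step_transform(k, params)

        def residue_atoms(template2d: dict, base: str, side: str, five_prime: bool):
            nonlocal serial
            atoms = []
            order = [] if five_prime else ["P"]
            order += ["C1'", "C2'", "C4'"]
            c1_pair = np.array([*template2d["C1'"], 0.0])
            for name in order:
                if name == "C1'":
                    p = c1_pair
                else:
                    off = _BACKBONE_OFFSETS[name]
                    if side == "R":
                        off = np.array([-off[0], off[1], -off[2]])
                    p = c1_pair + off
                serial += 1
                atoms.append(Atom(name, transform(p), serial=serial))
            for name in _BASE_ATOM_ORDER[base]:
                p = np.array([*template2d[name], 0.0])
                serial += 1
                atoms.append(Atom(name, transform(p), serial=serial))
            return atoms

        res_a.append(
            Residue(chain_ids[0], k + 1, base_a,
                    residue_atoms({k2: np.array(v) for k2, v in left2d.items()},
                                  base_a, "L", five_prime=(k == 0)))
        )
        # strand B runs antiparallel: step k holds its residue n - k
        res_b.append(
            Residue(chain_ids[1], n - k, base_b,
                    residue_atoms({k2: np.array(v) for k2, v in right2d.items()},
                                  base_b, "R", five_prime=(k == n - 1)))
        )
    res_b.sort(key=lambda r: r.index)
    return RnaStructure([Chain(chain_ids[0], res_a), Chain(chain_ids[1], res_b)])


def build_cug_duplex(n_repeats: int, cap: str = "", params: HelixParams = HelixParams()) -> RnaStructure:
    """(CUG)_n duplex, optionally capped (cap="GC" adds a 5' G and 3' C)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seq = "CUG" * n_repeats
    if cap:
        if len(cap) != 2 or set(cap) - set("ACGU"):
            raise ValueError("cap must be two bases, e.g. 'GC'")
        seq = cap[0] + seq + cap[1]
    return build_aform_duplex(seq, params)


# ---------------------------------------------------------------------------
# Type-targeted U-U perturbation
# ---------------------------------------------------------------------------

def perturb_uu(structure: RnaStructure, pair_index: int, target_type: str) -> RnaStructure:
    """Rigidly re-pose one U-U pair so it classifies as ``target_type`` (I-VI).

    The two uracil bases are replaced by the pair-frame template with the
    target's hydrogen-bond count, then translated together along the groove
    axis until the inclination displacement hits the target label's value
    (0 for none, +1.5 A major, -1.5 A minor).  Backbone atoms (and every
    other residue) are untouched.
    """
    from .uu import TYPE_REQUIREMENTS, find_uu_pairs, groove_displacement

    if target_type not in TYPE_REQUIREMENTS:
        raise ValueError(f"unknown U-U type {target_type!r}; expected I..VI")
    n_hb, incl_label = TYPE_REQUIREMENTS[target_type]
    out = structure.copy()
    pairs = find_uu_pairs(out)
    if not 0 <= pair_index < len(pairs):
        raise IndexError(f"pair index {pair_index} out of range ({len(pairs)} U-U pairs)")
    pair = pairs[pair_index]

    c1a = pair.res_a.atom("C1'").coords
    c1b = pair.res_b.atom("C1'").coords
    origin = 0.5 * (c1a + c1b)
    xhat = (c1b - c1a) / np.linalg.norm(c1b - c1a)
    # base-plane normal from the current ring atoms of both uracils
    ring_pts = np.vstack([
        pair.res_a.coords_of([a for a in ("N1", "C2", "N3", "C4", "C5", "C6")]),
        pair.res_b.coords_of([a for a in ("N1", "C2", "N3", "C4", "C5", "C6")]),
    ])
    centred = ring_pts - ring_pts.mean(axis=0)
    normal = np.linalg.svd(centred)[2][-1]
    zhat = normal - (normal @ xhat) * xhat
    zhat = zhat / np.linalg.norm(zhat)
    yhat = np.cross(zhat, xhat)
    # orient y toward the base side using the flanking canonical pairs,
    # which perturbation never touches (the U-U centroid itself may cross
    # the C1'-C1' axis after a groove shift)
    side = 0.0
    for fa, fb in (pair.flank_5, pair.flank_3):
        flank_mid = 0.5 * (fa.atom("C1'").coords + fb.atom("C1'").coords)
        centroid = 0.5 * (fa.base_centroid() + fb.base_centroid())
        side += (centroid - flank_mid) @ yhat
    if side < 0:
        yhat, zhat = -yhat, -zhat

    left2d, right2d = uu_pair_template(n_hb)
    for res, template in ((pair.res_a, left2d), (pair.res_b, right2d)):
        for atom in res.atoms:
            if atom.name in ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"):
                tx, ty = template[atom.name]
                atom.coords = origin + tx * xhat + ty * yhat

    target_disp = {"none": 0.0, "major": 1.5, "minor": -1.5}[incl_label]
    current, ghat = groove_displacement(pair)
    shift = (target_disp - current) * ghat
    for res in (pair.res_a, pair.res_b):
        for atom in res.atoms:
            if atom.name in ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"):
                atom.coords = atom.coords + shift
    return out


# ---------------------------------------------------------------------------
# Gaussian ensembles and trajectories
# ---------------------------------------------------------------------------

@dataclass
class GenerativeModel:
    """Low-rank Gaussian model of conformational variation about a reference.

    Conformers are reference + sum_k z_k sqrt(var_k) d_k + isotropic noise,
    z ~ N(0, 1).  Stands in for crystal-fragment ensembles and MD snapshot
    sets with a known mode structure.
    """

    reference: NodeSet
    directions: np.ndarray          # (3N, k), orthonormal columns
    variances: np.ndarray           # (k,), A^2, descending
    noise_variance: float = 0.0     # per coordinate, A^2
    seed: int = 0

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        k = self.directions.shape[1]
        gram = self.directions.T @ self.directions
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("mode directions must be orthonormal")
        if self.noise_variance < 0 or np.any(self.variances < 0):
            raise ValueError("variances must be non-negative")

    @classmethod
    def from_fractions(
        cls,
        reference: NodeSet,
        directions: np.ndarray,
        fractions_percent: tuple[float, ...],
        total_variance: float | None = None,
        seed: int = 0,
    ) -> "GenerativeModel":
        """Prescribe the *PCA variance fractions* the ensemble should show.

        The isotropic noise floor is set so the remaining variance spreads
        evenly over the other 3N - k directions; mode variances are reduced
        by the floor so the top-k PCA fractions come out exactly as asked
        (in expectation).  ``total_variance`` defaults to 1 A^2 per node.
        """
        directions = np.asarray(directions, dtype=float)
        f = np.asarray(fractions_percent, dtype=float) / 100.0
        if np.any(f <= 0) or f.sum() >= 1:
            raise ValueError("fractions must be positive and sum to < 100%")
        dim = directions.shape[0]
        k = directions.shape[1]
        if len(f) != k:
            raise ValueError("one fraction per direction required")
        total = float(total_variance) if total_variance is not None else dim / 3.0
        noise = total * (1.0 - f.sum()) / (dim - k)
        variances = total * f - noise
        if np.any(variances <= 0):
            raise ValueError("fractions too small to sit above the noise floor")
        return cls(reference, directions, variances, noise_variance=noise, seed=seed)

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        flat = self.reference.coords.ravel()
        z = rng.standard_normal((m, len(self.variances)))
        x = flat + (z * np.sqrt(self.variances)) @ self.directions.T
        if self.noise_variance > 0:
            x = x + math.sqrt(self.noise_variance) * rng.standard_normal(x.shape)
        return x


def gaussian_ensemble(model: GenerativeModel, m: int) -> Ensemble:
    """Draw m conformers from the generative model (seeded, reproducible)."""
    if m < 2:
        raise ValueError("need m >= 2 conformers")
    rng = np.random.default_rng(model.seed)
    x = model.sample(m, rng)
    return Ensemble(
        x.reshape(m, -1, 3),
        list(model.reference.labels),
        aligned=True,
        source=f"gaussian(seed={model.seed})",
    )


def synthetic_trajectory(
    model: GenerativeModel,
    n_frames: int,
    path: str | Path,
    drift_amplitude: float = 0.0,
    drift_period: int | None = None,
) -> tuple[Path, list[NodeSet]]:
    """Write a synthetic multi-model PDB trajectory; also return the frames.

    Frames are Gaussian draws, optionally superposed with a slow sinusoidal
    drift along the first mode direction (emulating quasi-periodic helix
    breathing).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(model.seed)
    x = model.sample(n_frames, rng)
    if drift_amplitude:
        period = drift_period or n_frames
        t = np.arange(n_frames)
        x = x + (drift_amplitude * np.sin(2 * np.pi * t / period))[:, None] * \
            model.directions[:, 0]
    frames = [NodeSet(x[t].reshape(-1, 3), list(model.reference.labels))
              for t in range(n_frames)]
    ensemble = Ensemble(x.reshape(n_frames, -1, 3), list(model.reference.labels),
                        aligned=False, source="synthetic trajectory")
    out = write_node_pdb(ensemble, path)
    return out, frames
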