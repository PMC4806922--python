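"""RNA structures, coarse-grained node selection and ensemble alignment.

The in-memory model is deliberately small: an :class:`RnaStructure` is an
ordered list of chains, each an ordered list of residues carrying named atoms
with coordinates.  Everything downstream (elastic networks, ensemble PCA,
U-U pair geometry) operates either on these structures or on the
:class:`NodeSet` / :class:`Ensemble` containers produced here.

Reading uses Bio.PDB; writing is a direct fixed-width ATOM-record formatter
(our records map one-to-one onto PDB lines).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")

#: Residue names silently dropped on read (solvent / common ions).
SOLVENT_NAMES = frozenset(
    {"HOH", "WAT", "DOD", "NA", "K", "MG", "CA", "CL", "MN", "ZN", "SR",
     "SO4", "PO4", "SPM", "SPD", "EDO", "GOL"}
)

# Heavy-atom ring definitions used for centroids and pair geometry.
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")


class PdbError(IOError):
    """Unreadable or structurally unusable PDB input."""


class EmptyStructureError(PdbError):
    """A file (or model) contained no RNA residues."""


class ModifiedResidueError(PdbError):
    """A modified nucleotide was encountered with no alias mapping it."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    coords: np.ndarray
    serial: int = 0
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            self.element = _element_from_name(self.name)


@dataclass
class Residue:
    chain_id: str
    index: int                # author resSeq, preserved for output
    name: str                 # one of A/C/G/U after normalization
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_of(self, names: Iterable[str]) -> np.ndarray:
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise KeyError(f"residue {self.chain_id}{self.index} {self.name}: missing atom {n}")
            out.append(a.coords)
        return np.asarray(out)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def ring_atom_names(self) -> tuple[str, ...]:
        return PURINE_RING if self.name in ("A", "G") else PYRIMIDINE_RING

    def base_centroid(self) -> np.ndarray:
        names = [n for n in self.ring_atom_names() if self.atom(n) is not None]
        if not names:
            raise KeyError(f"residue {self.chain_id}{self.index}: no base ring atoms")
        return self.coords_of(names).mean(axis=0)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.name for r in self.residues)


@dataclass
class RnaStructure:
    chains: list[Chain] = field(default_factory=list)
    model_id: int = 0

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def copy(self) -> "RnaStructure":
        return copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "RnaStructure":
        out = self.copy()
        for r in out.residues():
            for a in r.atoms:
                a.coords = rotation @ a.coords + translation
        return out


@dataclass(frozen=True)
class CoarseGrainScheme:
    """Which atoms represent a nucleotide as network nodes.

    CG1 keeps backbone probes only; CG2 adds base probes (C4, N3) so that
    base-pair breathing is visible to the network; ALL keeps every heavy atom.
    """

    name: str
    atoms_per_residue: tuple[str, ...] | None   # None means all heavy atoms

    def __post_init__(self) -> None:
        if self.atoms_per_residue is not None and len(self.atoms_per_residue) == 0:
            raise ValueError("scheme atom set must be non-empty")


SCHEMES = {
    "ALL": CoarseGrainScheme("ALL", None),
    "CG1": CoarseGrainScheme("CG1", ("P", "C2'", "C4'")),
    "CG2": CoarseGrainScheme("CG2", ("P", "C2'", "C4", "N3")),
}


def get_scheme(scheme: str | CoarseGrainScheme) -> CoarseGrainScheme:
    if isinstance(scheme, CoarseGrainScheme):
        return scheme
    try:
        return SCHEMES[scheme.upper()]
    except KeyError:
        raise ValueError(f"unknown coarse-grain scheme {scheme!r}; choose from {sorted(SCHEMES)}")


NodeLabel = tuple[str, int, str, str]  # (chain_id, residue_index, residue_name, atom_name)


@dataclass
class NodeSet:
    coords: np.ndarray                    # (N, 3) Angstrom
    labels: list[NodeLabel]
    scheme: CoarseGrainScheme | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("NodeSet coords must be (N, 3)")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def subset_indices(self, atom_name: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab[3] == atom_name], dtype=int)

    def with_coords(self, coords: np.ndarray) -> "NodeSet":
        return NodeSet(np.asarray(coords, dtype=float), list(self.labels), self.scheme)


@dataclass
class Ensemble:
    """m aligned conformers sharing one set of node labels."""

    coords: np.ndarray                    # (m, N, 3)
    node_labels: list[NodeLabel]
    aligned: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("Ensemble coords must be (m, N, 3)")
        if self.coords.shape[1] != len(self.node_labels):
            raise ValueError("node_labels do not match coordinate array")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def conformer(self, t: int) -> NodeSet:
        return NodeSet(self.coords[t].copy(), list(self.node_labels))


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _pick_altloc(bp_atom):
    """Resolve a Bio.PDB (possibly disordered) atom to a single location.

    Highest occupancy wins; ties break toward the alphabetically first
    altloc letter.
    """
    if not bp_atom.is_disordered():
        return bp_atom, False
    children = list(bp_atom.child_dict.values())
    best = max(children, key=lambda a: (a.get_occupancy() or 0.0, -ord((a.get_altloc() or "Z")[0])))
    return best, True


def read_pdb(path: str | Path, aliases: dict[str, str] | None = None) -> list[RnaStructure]:
    """Read a (possibly multi-model) PDB file into one structure per MODEL.

    Non-RNA residues (waters, ions) are dropped with a logged count.  A
    HETATM residue that looks like a modified nucleotide (it has a C1' atom)
    raises :class:`ModifiedResidueError` unless ``aliases`` maps its name to
    one of A/C/G/U — silent base substitution would corrupt U-U typing.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise PdbError(f"no such file: {path}")
    aliases = aliases or {}
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on garbage
        raise PdbError(f"could not parse {path}: {exc}") from exc

    structures: list[RnaStructure] = []
    n_dropped = 0
    n_altloc = 0
    for model in bio_structure:
        chains: list[Chain] = []
        for bp_chain in model:
            residues: list[Residue] = []
            for bp_res in bp_chain:
                raw_name = bp_res.get_resname().strip()
                name = aliases.get(raw_name, raw_name)
                if name not in RNA_BASES:
                    if raw_name in SOLVENT_NAMES or "C1'" not in bp_res:
                        n_dropped += 1
                        continue
                    raise ModifiedResidueError(
                        f"residue {raw_name} {bp_res.get_id()[1]} in chain "
                        f"{bp_chain.id}: not a standard RNA base and no alias supplied"
                    )
                atoms = []
                for bp_atom in bp_res:
                    picked, was_disordered = _pick_altloc(bp_atom)
                    n_altloc += int(was_disordered)
                    atoms.append(
                        Atom(
                            name=picked.get_name(),
                            coords=np.array(picked.get_coord(), dtype=float),
                            serial=picked.get_serial_number() or 0,
                            occupancy=picked.get_occupancy() or 1.0,
                            b_factor=picked.get_bfactor() or 0.0,
                        )
                    )
                if atoms:
                    residues.append(Residue(bp_chain.id, bp_res.get_id()[1], name, atoms))
            if residues:
                residues.sort(key=lambda r: r.index)
                chains.append(Chain(bp_chain.id, residues))
        if chains:
            structures.append(RnaStructure(chains, model_id=model.id))
    if n_dropped:
        logger.info("read_pdb(%s): dropped %d non-RNA residues", path.name, n_dropped)
    if n_altloc:
        logger.info("read_pdb(%s): resolved %d alternate locations", path.name, n_altloc)
    if not structures:
        raise EmptyStructureError(f"{path}: no RNA residues found")
    return structures


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # Single-letter elements start in column 14 unless the name is 4 chars.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(serial: int, atom: Atom, res: Residue) -> str:
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:5d} {_format_atom_name(atom.name)} {res.name:>3s} "
        f"{res.chain_id[:1]}{res.index:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structures: RnaStructure | Sequence[RnaStructure], path: str | Path) -> Path:
    """Write one or more structures as a (multi-model) PDB file."""
    if isinstance(structures, RnaStructure):
        structures = [structures]
    path = Path(path)
    multi = len(structures) > 1
    lines: list[str] = []
    for i, structure in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL {i:8d}")
        serial = 0
        for chain in structure.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(_atom_line(serial, atom, res))
            serial += 1
            lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                         f"{chain.id[:1]}{chain.residues[-1].index:4d}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_node_pdb(ensemble: Ensemble, path: str | Path) -> Path:
    """Export an ensemble of coarse-grained nodes as a multi-model PDB."""
    structures = []
    for t in range(ensemble.n_conformers):
        structures.append(structure_from_nodes(ensemble.conformer(t), model_id=t))
    return write_pdb(structures, path)


def structure_from_nodes(nodes: NodeSet, model_id: int = 0) -> RnaStructure:
    """Reconstruct a (nodes-only) RnaStructure from labelled node coordinates."""
    chains: dict[str, Chain] = {}
    residues: dict[tuple[str, int], Residue] = {}
    for (chain_id, res_index, res_name, atom_name), xyz in zip(nodes.labels, nodes.coords):
        key = (chain_id, res_index)
        if key not in residues:
            res = Residue(chain_id, res_index, res_name)
            residues[key] = res
            chains.setdefault(chain_id, Chain(chain_id)).residues.append(res)
        residues[key].atoms.append(Atom(atom_name, np.array(xyz)))
    return RnaStructure(list(chains.values()), model_id=model_id)


def write_label_table(labels: Sequence[NodeLabel], path: str | Path) -> Path:
    path = Path(path)
    rows = ["chain\tresSeq\tresname\tatom"]
    rows += [f"{c}\t{i}\t{r}\t{a}" for (c, i, r, a) in labels]
    path.write_text("\n".join(rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# Node selection
# ---------------------------------------------------------------------------

def select_nodes(structure: RnaStructure, scheme: str | CoarseGrainScheme) -> NodeSet:
    """Pick the coarse-grained nodes of ``structure`` under ``scheme``.

    Residues missing a scheme atom (5'-terminal residues have no phosphate)
    contribute only the atoms they have; the omission is logged.
    """
    scheme = get_scheme(scheme)
    coords: list[np.ndarray] = []
    labels: list[NodeLabel] = []
    n_missing = 0
    for chain in structure.chains:
        for res in chain.residues:
            if scheme.atoms_per_residue is None:
                chosen = res.heavy_atoms
            else:
                chosen = []
                for name in scheme.atoms_per_residue:
                    a = res.atom(name)
                    if a is None:
                        n_missing += 1
                    else:
                        chosen.append(a)
            for a in chosen:
                coords.append(a.coords)
                labels.append((chain.id, res.index, res.name, a.name))
    if not coords:
        raise ValueError(f"scheme {scheme.name}: no nodes selected from structure")
    if n_missing:
        logger.info("select_nodes(%s): %d scheme atoms absent (e.g. 5'-terminal P)",
                    scheme.name, n_missing)
    return NodeSet(np.asarray(coords), labels, scheme)


def positional_nodes(nodes: NodeSet) -> NodeSet:
    """Relabel nodes by (chain order, running residue position).

    Conformers of the same topology from different sources (fragment
    windows, different crystals) rarely share author residue numbers;
    positional labels make them comparable.
    """
    out_labels: list[NodeLabel] = []
    seen: dict[tuple[str, int], int] = {}
    for chain_id, res_index, res_name, atom_name in nodes.labels:
        key = (chain_id, res_index)
        if key not in seen:
            seen[key] = len(seen) + 1
        out_labels.append((chain_id, seen[key], res_name, atom_name))
    return NodeSet(nodes.coords, out_labels, nodes.scheme)


def common_node_subset(conformers: Sequence[NodeSet]) -> list[NodeSet]:
    """Restrict every conformer to the node labels present in all of them.

    Fragments cut at chain termini lack 5'-phosphates that interior
    fragments carry; analyses need a shared node set.
    """
    common = set(conformers[0].labels)
    for ns in conformers[1:]:
        common &= set(ns.labels)
    if not common:
        raise ValueError("conformers share no node labels")
    out = []
    for ns in conformers:
        idx = [i for i, lab in enumerate(ns.labels) if lab in common]
        out.append(NodeSet(ns.coords[idx], [ns.labels[i] for i in idx], ns.scheme))
    return out


# ---------------------------------------------------------------------------
# Duplex pairing and fragment extraction
# ---------------------------------------------------------------------------

WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})


def _is_pairable(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS or (a, b) == ("U", "U")


@dataclass
class DuplexPairing:
    chain_a: Chain
    chain_b: Chain
    offset: int                         # i + j == offset for paired (i, j)
    pairs: list[tuple[int, int]]        # paired positions (index into each chain)

    def partner(self, i: int) -> int | None:
        j = self.offset - i
        return j if (i, j) in set(self.pairs) else None


def pair_chains(structure: RnaStructure, min_pairs: int = 6) -> DuplexPairing:
    """Find the antiparallel register pairing the first two chains.

    Complementarity is Watson-Crick with U·U accepted at uridine positions;
    the register maximizing the number of pairable positions wins and must
    reach ``min_pairs``.
    """
    if len(structure.chains) < 2:
        raise ValueError("duplex detection needs two chains")
    ca, cb = structure.chains[0], structure.chains[1]
    sa, sb = ca.sequence, cb.sequence
    best: tuple[int, list[tuple[int, int]]] | None = None
    for d in range(len(sa) + len(sb) - 1):
        pairs = [
            (i, d - i)
            for i in range(max(0, d - len(sb) + 1), min(len(sa), d + 1))
            if _is_pairable(sa[i], sb[d - i])
        ]
        if best is None or len(pairs) > len(best[1]):
            best = (d, pairs)
    if best is None or len(best[1]) < min_pairs:
        raise ValueError(
            f"chains {ca.id}/{cb.id} do not form an antiparallel duplex "
            f"(needed >= {min_pairs} pairable positions)"
        )
    return DuplexPairing(ca, cb, best[0], best[1])


def extract_cug_fragments(
    structure: RnaStructure, n_repeats: int = 3, stride: int = 1
) -> list[RnaStructure]:
    """Cut double-stranded (CUG)_n windows out of a CUG-repeat duplex.

    Windows advance by ``stride`` triplets along the repeat tract of the
    reference strand; the paired window comes from the complementary strand.
    A clean (CUG)_R tract yields max(0, R - n_repeats + 1) fragments at
    stride 1.  Returns an empty list when no tract is long enough.
    """
    if n_repeats < 1 or stride < 1:
        raise ValueError("n_repeats and stride must be positive")
    try:
        pairing = pair_chains(structure)
    except ValueError:
        return []
    seq = pairing.chain_a.sequence
    pair_map = dict(pairing.pairs)
    fragments: list[RnaStructure] = []
    # maximal runs of the CUG triplet on the reference strand
    runs: list[tuple[int, int]] = []   # (start, n_triplets)
    i = 0
    while i + 3 <= len(seq):
        if seq[i:i + 3] == "CUG":
            start = i
            while i + 3 <= len(seq) and seq[i:i + 3] == "CUG":
                i += 3
            runs.append((start, (i - start) // 3))
        else:
            i += 1
    for start, n_trip in runs:
        for w in range(0, n_trip - n_repeats + 1, stride):
            ia = start + 3 * w
            a_idx = list(range(ia, ia + 3 * n_repeats))
            b_idx = [pair_map.get(i) for i in a_idx]
            if any(j is None for j in b_idx):
                continue
            frag_a = [copy.deepcopy(pairing.chain_a.residues[i]) for i in a_idx]
            frag_b = [copy.deepcopy(pairing.chain_b.residues[j]) for j in sorted(b_idx)]
            fragments.append(
                RnaStructure(
                    [Chain(pairing.chain_a.id, frag_a), Chain(pairing.chain_b.id, frag_b)],
                    model_id=structure.model_id,
                )
            )
    return fragments


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``reference ~ rotation @ mobile + translation`` and a proper rotation
    (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate shape mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points of shape (N, 3)")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    translation = cr - rotation @ cm
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def superpose_coords(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    rotation, translation, _ = kabsch_superpose(mobile, reference)
    return np.asarray(mobile) @ rotation.T + translation


def align_ensemble(
    conformers: Sequence[NodeSet],
    tol: float = 1e-6,
    max_iter: int = 100,
    source: str = "",
) -> Ensemble:
    """Iteratively superpose conformers onto their evolving mean structure.

    Converges when the mean shifts by less than ``tol`` (RMSD, Angstrom); the
    converged mean is then a fixed point of superposition.
    """
    if len(conformers) < 1:
        raise ValueError("empty conformer list")
    labels = conformers[0].labels
    for k, c in enumerate(conformers[1:], start=1):
        if c.labels != labels:
            bad = next(
                (pair for pair in zip(labels, c.labels) if pair[0] != pair[1]),
                (None, None),
            )
            raise ValueError(
                f"conformer {k}: node labels differ from conformer 0 "
                f"(first mismatch: {bad[0]} vs {bad[1]})"
            )
    coords = np.stack([c.coords for c in conformers]).astype(float)
    mean = coords[0].copy()
    for _ in range(max_iter):
        for t in range(coords.shape[0]):
            coords[t] = superpose_coords(coords[t], mean)
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return Ensemble(coords, list(labels), aligned=True, source=source)
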