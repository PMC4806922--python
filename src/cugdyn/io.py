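"""Plain-text tabular export/import: mode sets, spectra, profiles, scans.

Every table is TSV with ``#``-comment header lines carrying the generating
parameters, so outputs diff cleanly between runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .anm import ModeSet
from .ensembles import FluctuationProfile, VarianceSpectrum
from .structures import NodeLabel


def _header(params: Mapping[str, object]) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in params.items())


def save_modeset(modes: ModeSet, path: str | Path,
                 spectrum: VarianceSpectrum | None = None) -> tuple[Path, Path]:
    """Write a mode set as two TSVs: per-mode summary and eigenvector components.

    The vectors file uses 1-based mode numbers; mode 0 rows carry the
    reference (mean) coordinates when the set has them.
    """
    path = Path(path)
    vec_path = path.with_suffix(path.suffix + ".vectors.tsv")
    params = {"kind": modes.kind, "n_dropped": modes.n_dropped,
              "n_nodes": modes.n_nodes, "n_modes": modes.n_modes}
    rows = ["index\teigenvalue\tvariance_fraction"]
    fractions = (spectrum.fractions if spectrum is not None
                 else [np.nan] * modes.n_modes)
    for i, (lam, frac) in enumerate(zip(modes.eigenvalues, fractions), start=1):
        rows.append(f"{i}\t{lam:.10g}\t{frac:.6g}" if np.isfinite(frac)
                    else f"{i}\t{lam:.10g}\tNA")
    path.write_text(_header(params) + "\n".join(rows) + "\n")

    vrows = ["mode\tchain\tresSeq\tresname\tatom\tdx\tdy\tdz"]
    if modes.mean is not None:
        for lab, xyz in zip(modes.node_labels, modes.mean.reshape(-1, 3)):
            vrows.append("0\t" + "\t".join(map(str, lab)) +
                         "\t" + "\t".join(f"{v:.6f}" for v in xyz))
    for k in range(modes.n_modes):
        vec = modes.eigenvectors[:, k].reshape(-1, 3)
        for lab, xyz in zip(modes.node_labels, vec):
            vrows.append(f"{k + 1}\t" + "\t".join(map(str, lab)) +
                         "\t" + "\t".join(f"{v:.10g}" for v in xyz))
    vec_path.write_text(_header(params) + "\n".join(vrows) + "\n")
    return path, vec_path


def load_modeset(path: str | Path) -> ModeSet:
    """Reload a mode set written by :func:`save_modeset`."""
    path = Path(path)
    vec_path = path.with_suffix(path.suffix + ".vectors.tsv")
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line[1:].split("=", 1)
            meta[k.strip()] = v.strip()
    summary = pd.read_csv(path, sep="\t", comment="#")
    vectors = pd.read_csv(vec_path, sep="\t", comment="#")
    first = vectors[vectors["mode"] == vectors[vectors["mode"] > 0]["mode"].iloc[0]]
    labels: list[NodeLabel] = [
        (str(r.chain), int(r.resSeq), str(r.resname), str(r.atom))
        for r in first.itertuples()
    ]
    n_modes = len(summary)
    dim = 3 * len(labels)
    eigvecs = np.empty((dim, n_modes))
    for k in range(1, n_modes + 1):
        block = vectors[vectors["mode"] == k][["dx", "dy", "dz"]].to_numpy()
        eigvecs[:, k - 1] = block.ravel()
    mean = None
    mean_block = vectors[vectors["mode"] == 0]
    if len(mean_block):
        mean = mean_block[["dx", "dy", "dz"]].to_numpy().ravel()
    return ModeSet(
        eigenvalues=summary["eigenvalue"].to_numpy(),
        eigenvectors=eigvecs,
        kind=meta.get("kind", "ANM"),
        n_dropped=int(meta.get("n_dropped", 0)),
        node_labels=labels,
        mean=mean,
    )


def save_profile(profile: FluctuationProfile, path: str | Path,
                 params: Mapping[str, object] | None = None) -> Path:
    path = Path(path)
    rows = ["chain\tresSeq\tresname\tatom\tsubset\trmsf"]
    for lab, v in zip(profile.node_labels, profile.values):
        rows.append("\t".join(map(str, lab)) + f"\t{profile.subset}\t{v:.6f}")
    path.write_text(_header(params or {}) + "\n".join(rows) + "\n")
    return path


def save_table(df: pd.DataFrame, path: str | Path,
               params: Mapping[str, object] | None = None, sep: str = "\t") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(params or {}))
        df.to_csv(fh, sep=sep, index=False)
    return path


def write_manifest(outputs: Sequence[str | Path], params: Mapping[str, object],
                   manifest_path: str | Path) -> Path:
    """Machine-readable record of a run: parameters plus output hashes."""
    entries = {}
    for out in outputs:
        out = Path(out)
        entries[out.name] = hashlib.sha256(out.read_bytes()).hexdigest()
    payload = {"parameters": {k: str(v) for k, v in params.items()},
               "outputs": entries}
    manifest_path = Path(manifest_path)
    manifest_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return manifest_path
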