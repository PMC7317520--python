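"""Structured report writing: fits, bootstrap ensembles, Pareto fronts.

Every artifact is plain delimited text or JSON, deterministic in name
and content, and re-readable losslessly by the package's own readers; a
manifest with SHA-256 checksums accompanies each report set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import DMFA
from .selection import ParetoFront
from .uncertainty import BootstrapEnsemble

__all__ = ["write_fit_report", "write_ensemble_report", "write_front_report",
           "read_front_table", "write_manifest"]

_FLOAT = "%.15g"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, files: list) -> Path:
    outdir = Path(outdir)
    manifest = {f.name: _sha256(f) for f in sorted(files)}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_fit_report(fit: DMFA, outdir, curve_times=None) -> list:
    """Node values, sampled fitted curves, and a machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    nodes = pd.DataFrame(fit.node_values_,
                         index=[f"dir{k + 1}" for k
                                in range(fit.node_values_.shape[0])],
                         columns=fit.grid_.nodes)
    p = outdir / "node_values.tsv"
    nodes.to_csv(p, sep="\t", float_format=_FLOAT)
    files.append(p)

    if curve_times is None:
        curve_times = np.linspace(fit.grid_.nodes[0], fit.grid_.nodes[-1], 101)
    curves = fit.predict(curve_times)
    p = outdir / "fitted_curves.tsv"
    curves.to_csv(p, sep="\t", float_format=_FLOAT)
    files.append(p)

    summary = {
        "mode": fit.mode,
        "ssr": fit.ssr_,
        "alpha": fit.alpha_,
        "grid_nodes": fit.grid_.nodes.tolist(),
        "species": fit.species_ids_,
        "c0": fit.c0_.tolist(),
    }
    p = outdir / "fit_summary.json"
    p.write_text(json.dumps(summary, indent=2) + "\n")
    files.append(p)
    files.append(write_manifest(outdir, files))
    return files


def write_ensemble_report(ens: BootstrapEnsemble, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for quantity, band in sorted(ens.bands.items()):
        p = outdir / f"band_{quantity.replace(':', '_')}.tsv"
        band.rename_axis("time").to_csv(p, sep="\t", float_format=_FLOAT)
        files.append(p)
    summary = {"n_samples": ens.n_samples, "n_failed": ens.n_failed,
               "quantities": sorted(ens.bands)}
    p = outdir / "ensemble_summary.json"
    p.write_text(json.dumps(summary, indent=2) + "\n")
    files.append(p)
    files.append(write_manifest(outdir, files))
    return files


def write_front_report(front: ParetoFront, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / "pareto_front.tsv"
    front.to_frame().to_csv(p, sep="\t", index=False, float_format=_FLOAT)
    meta = outdir / "front_provenance.json"
    meta.write_text(json.dumps(front.provenance, indent=2, default=str) + "\n")
    files = [p, meta, write_manifest(outdir, [p, meta])]
    return files


def read_front_table(path, em_ids) -> ParetoFront:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    entries = []
    for row in df.itertuples(index=False):
        xi = np.array([int(b) for b in row.chromosome])
        entries.append((xi, int(row.size), float(row.ssr)))
    return ParetoFront(entries=entries, em_ids=list(em_ids))
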