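"""Delimited-text I/O for chromatogram sets, tables and ground truth.

Everything is plain TSV (UTF-8, decimal point, header rows) or JSON:
one two-column file per chromatogram (``rt_minutes``,
``intensity_AU``), a design table, and a JSON sidecar for the planted
ground truth of synthetic experiments.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Chromatogram, ChromatogramSet
from .simdata import GroundTruth, PiecewiseLinearWarp

__all__ = [
    "write_chromatogram_set",
    "read_chromatogram_set",
    "write_ground_truth",
    "read_ground_truth",
    "write_table",
    "read_table",
]


def _trace_filename(sample_id: str, wavelength: int) -> str:
    return f"{sample_id}__{wavelength}nm.tsv"


def write_chromatogram_set(directory: str | Path, chromset: ChromatogramSet) -> Path:
    """Write one TSV per trace plus ``design.tsv``; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c in chromset:
        df = pd.DataFrame({"rt_minutes": c.rt, "intensity_AU": c.intensity})
        df.to_csv(directory / _trace_filename(c.sample_id, c.wavelength),
                  sep="\t", index=False)
    chromset.design.to_csv(directory / "design.tsv", sep="\t", index=False)
    return directory


def read_chromatogram_set(
    directory: str | Path, design_path: str | Path | None = None
) -> ChromatogramSet:
    """Read a chromatogram directory back into memory.

    Every sample listed in the design must have a trace file per
    wavelength present on disk (error naming the sample otherwise);
    trace files not listed in the design are ignored with a warning.
    Mismatched grid lengths are rejected.
    """
    directory = Path(directory)
    design_path = Path(design_path) if design_path else directory / "design.tsv"
    if not design_path.exists():
        raise FileNotFoundError(f"design table not found: {design_path}")
    design = pd.read_csv(design_path, sep="\t")

    files = {p.name: p for p in directory.glob("*__*nm.tsv")}
    wavelengths = sorted(
        {int(name.rsplit("__", 1)[1].removesuffix("nm.tsv")) for name in files}
    )
    chroms = []
    expected = set()
    for row in design.itertuples(index=False):
        for wl in wavelengths:
            fname = _trace_filename(row.sample_id, wl)
            expected.add(fname)
            if fname not in files:
                raise FileNotFoundError(
                    f"sample {row.sample_id!r} listed in design but trace file "
                    f"{fname!r} is missing"
                )
            df = pd.read_csv(files[fname], sep="\t")
            chroms.append(
                Chromatogram(
                    rt=df["rt_minutes"].to_numpy(),
                    intensity=df["intensity_AU"].to_numpy(),
                    wavelength=wl,
                    sample_id=row.sample_id,
                    sample_mass=float(row.sample_mass),
                )
            )
    extras = set(files) - expected
    if extras:
        warnings.warn(
            f"{len(extras)} trace file(s) not listed in the design were ignored",
            stacklevel=2,
        )
    lengths = {c.n_points for c in chroms}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent grid lengths across traces: {lengths}")
    return ChromatogramSet(chroms, design)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "categories": truth.categories,
        "effect_maps": {
            m: {
                "varieties": list(em.index),
                "days": [int(d) for d in em.columns],
                "values": em.to_numpy().tolist(),
            }
            for m, em in truth.effect_maps.items()
        },
        "latent_rt": truth.latent_rt,
        "apex_rt": truth.apex_rt,
        "amplitudes": {
            m: {str(wl): a for wl, a in d.items()}
            for m, d in truth.amplitudes.items()
        },
        "warps": {sid: w.to_dict() for sid, w in truth.warps.items()},
        "phenotype_effects": (
            truth.phenotype_effects.to_dict(orient="records")
            if truth.phenotype_effects is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    truth = GroundTruth()
    truth.categories = dict(payload["categories"])
    for m, em in payload["effect_maps"].items():
        truth.effect_maps[m] = pd.DataFrame(
            em["values"], index=em["varieties"], columns=em["days"]
        )
    truth.latent_rt = {m: float(v) for m, v in payload["latent_rt"].items()}
    truth.apex_rt = {m: float(v) for m, v in payload.get("apex_rt", {}).items()}
    truth.amplitudes = {
        m: {int(wl): float(a) for wl, a in d.items()}
        for m, d in payload["amplitudes"].items()
    }
    truth.warps = {
        sid: PiecewiseLinearWarp(np.array(w["nodes"]), np.array(w["values"]))
        for sid, w in payload["warps"].items()
    }
    if payload.get("phenotype_effects") is not None:
        truth.phenotype_effects = pd.DataFrame(payload["phenotype_effects"])
    return truth


def write_table(path: str | Path, table: pd.DataFrame, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
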