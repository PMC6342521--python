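"""File formats: YAML run configs, aggregate-table CSVs, TIFF stacks.

Aggregate tables travel as CSV with columns ``sample_label``,
``dilution_factor`` and ``size`` (one row per aggregate).  Stacks are
multi-page 16-bit TIFFs; the voxel size comes from a JSON sidecar
(``{"voxel_size_um": [dz, dy, dx]}``) or, failing that, from ImageJ-style
TIFF metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .aggstats import AggregateTable, VolumeWeightedECDF
from .errors import ConfigurationError
from .polymers import PolymerSpec, SolutionCondition
from .potentials import ColloidBrushSpec
from .brush import BrushDerivation
from .segmentation import ImageStack

__all__ = [
    "load_config",
    "polymer_specs_from_config",
    "brush_spec_from_config",
    "brush_derivation_from_config",
    "read_aggregate_tables",
    "write_aggregate_tables",
    "ecdf_frame",
    "read_stack",
    "write_stack",
]


def load_config(path) -> dict:
    """Parse a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return cfg


def _build(cls, mapping: dict, where: str):
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc


def polymer_specs_from_config(cfg: dict) -> list[PolymerSpec]:
    """The ``polymers:`` list of a config as PolymerSpec objects."""
    if "polymers" not in cfg:
        raise ConfigurationError("config has no 'polymers' section")
    return [_build(PolymerSpec, entry, f"polymers[{i}]")
            for i, entry in enumerate(cfg["polymers"])]


def brush_spec_from_config(cfg: dict) -> ColloidBrushSpec:
    if "brush" not in cfg:
        raise ConfigurationError("config has no 'brush' section")
    return _build(ColloidBrushSpec, cfg["brush"], "brush")


def brush_derivation_from_config(cfg: dict) -> BrushDerivation:
    if "brush_derivation" not in cfg:
        raise ConfigurationError("config has no 'brush_derivation' section")
    return _build(BrushDerivation, cfg["brush_derivation"], "brush_derivation")


def condition_from_config(cfg: dict, concentration: float = 0.0) -> SolutionCondition:
    cond = dict(cfg.get("condition", {}))
    cond.setdefault("concentration", concentration)
    return _build(SolutionCondition, cond, "condition")


def write_aggregate_tables(tables, path) -> None:
    """Write one or more AggregateTables to a single long-format CSV."""
    if isinstance(tables, AggregateTable):
        tables = [tables]
    frames = [
        pd.DataFrame({
            "sample_label": t.sample_label,
            "dilution_factor": t.dilution_factor,
            "size": t.sizes,
        })
        for t in tables
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_aggregate_tables(path) -> list[AggregateTable]:
    """Read a long-format CSV back into AggregateTables (one per label+dilution)."""
    df = pd.read_csv(path)
    missing = {"sample_label", "dilution_factor", "size"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for (label, dilution), group in df.groupby(["sample_label", "dilution_factor"], sort=True):
        tables.append(AggregateTable(group["size"].to_numpy(), str(label), float(dilution)))
    return tables


def ecdf_frame(ecdf: VolumeWeightedECDF) -> pd.DataFrame:
    """ECDF step table as a DataFrame (size, cumulative_volume_fraction)."""
    atoms, cum = ecdf.steps
    return pd.DataFrame({"size": atoms, "cumulative_volume_fraction": cum})


def write_stack(stack: ImageStack, tiff_path, sidecar: bool = True) -> None:
    """Write a stack as multi-page TIFF, with a voxel-size JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(stack.voxels), photometric="minisblack")
    if sidecar:
        tiff_path.with_suffix(".json").write_text(
            json.dumps({"voxel_size_um": list(stack.voxel_size)})
        )


def read_stack(tiff_path, sidecar_path=None) -> ImageStack:
    """Read a multi-page TIFF plus voxel-size metadata into an ImageStack.

    Voxel size is looked for in (1) the given or adjacent ``.json`` sidecar,
    (2) ImageJ metadata (``spacing`` + resolution tags).  A stack without
    resolvable voxel size is an error naming the file.
    """
    tiff_path = Path(tiff_path)
    voxels = tifffile.imread(tiff_path)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        try:
            dz, dy, dx = meta["voxel_size_um"]
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"{sidecar}: bad voxel_size_um entry") from exc
        return ImageStack(voxels, (float(dz), float(dy), float(dx)))
    with tifffile.TiffFile(tiff_path) as tf:
        ij = tf.imagej_metadata or {}
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if "spacing" in ij and xres is not None and yres is not None:
            dx = xres.value[1] / xres.value[0]
            dy = yres.value[1] / yres.value[0]
            return ImageStack(voxels, (float(ij["spacing"]), float(dy), float(dx)))
    raise ConfigurationError(
        f"{tiff_path}: no voxel-size metadata (provide a JSON sidecar with voxel_size_um)"
    )
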