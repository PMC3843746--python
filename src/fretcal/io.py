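"""Readers and writers: multi-page TIFF stacks, versioned CSV tables, JSON models.

TIFF layout: one file per cell with pages channel-major (all donor planes,
then acceptor, then FRET), or three single-channel files.  A JSON sidecar
declares ``channel_order``, ``pixel_size_nm`` and ``z_step_nm`` so channel
identity is never inferred from page order silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    CHANNELS,
    ChannelStack,
    ConfigError,
    FormatError,
)

__all__ = [
    "write_stacks",
    "read_stacks",
    "write_sidecar",
    "read_sidecar",
    "write_table",
    "read_table",
    "save_json",
    "load_json",
]

TABLE_VERSION = 1
_TABLE_MAGIC = "# fretcal-table v"

SIDECAR_KEYS = ("channel_order", "pixel_size_nm", "z_step_nm")


def write_sidecar(path: str | Path, channel_order=CHANNELS,
                  pixel_size_nm: float = 160.0, z_step_nm: float = 200.0) -> None:
    meta = {
        "channel_order": list(channel_order),
        "pixel_size_nm": pixel_size_nm,
        "z_step_nm": z_step_nm,
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def read_sidecar(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    for key in SIDECAR_KEYS:
        if key not in meta:
            raise ConfigError(f"sidecar {path} is missing required key {key!r}")
    return meta


def write_stacks(path: str | Path, stacks: dict[str, ChannelStack],
                 sidecar: str | Path | None = None) -> None:
    """Write channel stacks as a channel-major multi-page TIFF plus sidecar.

    Voxels are rounded to uint16 (raw camera counts are integers); the
    sidecar defaults to ``<path>.json``.
    """
    order = [c for c in CHANNELS if c in stacks]
    pages = np.concatenate([stacks[c].voxels for c in order], axis=0)
    data = np.clip(np.round(pages), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data)
    first = stacks[order[0]]
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    write_sidecar(sidecar, order, first.pixel_size_nm, first.z_step_nm)


def read_stacks(path: str | Path, sidecar: str | Path | dict | None = None
                ) -> dict[str, ChannelStack]:
    """Read a channel-major multi-page TIFF into per-channel stacks."""
    if sidecar is None:
        sidecar = str(path) + ".json"
    meta = sidecar if isinstance(sidecar, dict) else read_sidecar(sidecar)
    for key in SIDECAR_KEYS:
        if key not in meta:
            raise ConfigError(f"sidecar is missing required key {key!r}")
    order = meta["channel_order"]
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % len(order) != 0:
        raise FormatError(
            f"{path}: {pages.shape[0]} pages not divisible by {len(order)} channels"
        )
    nz = pages.shape[0] // len(order)
    stacks = {}
    for i, channel in enumerate(order):
        stacks[channel] = ChannelStack(
            pages[i * nz : (i + 1) * nz].astype(float),
            pixel_size_nm=meta["pixel_size_nm"],
            z_step_nm=meta["z_step_nm"],
            channel=channel,
        )
    return stacks


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with a leading schema-version comment line."""
    with open(path, "w") as fh:
        fh.write(f"{_TABLE_MAGIC}{TABLE_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a versioned CSV; unknown or missing versions are rejected loudly."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(_TABLE_MAGIC):
            raise FormatError(f"{path}: missing '{_TABLE_MAGIC}<n>' version header")
        version = first[len(_TABLE_MAGIC):]
        if version != str(TABLE_VERSION):
            raise FormatError(
                f"{path}: unsupported table version {version!r} (expected {TABLE_VERSION})"
            )
        return pd.read_csv(fh)


def save_json(obj, path: str | Path) -> None:
    """Serialize any toolkit object exposing ``to_dict`` to JSON."""
    Path(path).write_text(json.dumps(obj.to_dict(), indent=2))


def load_json(path: str | Path):
    """Load a JSON file written by :func:`save_json` back into its class."""
    from .ring import RingConfig
    from .spectral import CalibrationResult, ForsterParams, SpectralCoefficients
    from .synth import CellTruth

    registry = {
        "SpectralCoefficients": SpectralCoefficients,
        "CalibrationResult": CalibrationResult,
        "ForsterParams": ForsterParams,
        "RingConfig": RingConfig,
        "CellTruth": CellTruth,
    }
    d = json.loads(Path(path).read_text())
    kind = d.get("type")
    if kind not in registry:
        raise FormatError(f"{path}: unknown or missing object type {kind!r}")
    return registry[kind].from_dict(d)
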