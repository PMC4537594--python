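"""Readers and writers for the pipeline's plain-text formats.

All tabular artifacts are TSV/CSV (UTF-8, '.' decimal, header row) with a
'#'-prefixed provenance header (tool version, config hash, seed) that every
reader skips; models and warps serialize to JSON; configs to YAML.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import FeatureMatrix, RtWarp
from .synth import IonMap

__all__ = [
    "SchemaError",
    "provenance_header",
    "write_table",
    "read_table",
    "write_ion_maps",
    "read_ion_maps",
    "write_feature_matrix",
    "read_feature_matrix",
    "warp_to_json",
    "warp_from_json",
    "config_hash",
    "write_config",
    "read_config",
]

_MAP_META_COLUMNS = ("map_id", "sample_id", "condition", "platform", "paired_map_id")
_ION_REQUIRED = ("ion_id", "mz", "rt_min", "z", "intensity")


class SchemaError(ValueError):
    """Input table violates the declared schema."""


def _to_plain(obj):
    if is_dataclass(obj):
        return _to_plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    canon = json.dumps(_to_plain(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance_header(seed: int | None = None, config=None) -> list[str]:
    lines = [f"# ionpanel version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config hash: {config_hash(config)}")
    return lines


def write_table(
    df: pd.DataFrame, path: str | Path, sep: str = "\t",
    seed: int | None = None, config=None, extra_comments: list[str] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance_header(seed, config) + (extra_comments or []):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def _read_comments(path: Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            out.append(line.rstrip("\n"))
    return out


# ---------------------------------------------------------------------------
# Ion maps
# ---------------------------------------------------------------------------

def write_ion_maps(
    maps: list[IonMap], path: str | Path, seed: int | None = None, config=None
) -> None:
    """Write any number of maps to one TSV; map metadata rides along as columns."""
    frames = []
    for mp in maps:
        df = mp.ions[list(IonMap.ION_COLUMNS)].copy()
        df.insert(0, "map_id", mp.map_id)
        df.insert(1, "sample_id", mp.sample_id)
        df.insert(2, "condition", mp.condition)
        df.insert(3, "platform", mp.platform)
        df.insert(4, "paired_map_id", mp.paired_map_id or "")
        frames.append(df)
    write_table(pd.concat(frames, ignore_index=True), path, seed=seed, config=config)


def read_ion_maps(path: str | Path) -> list[IonMap]:
    """Read ion maps from TSV, validating the schema row by row.

    Rows violating an invariant (non-positive m/z, charge < 1, negative
    intensity, unparseable numerics) are rejected with their 1-based line
    numbers collected into the raised :class:`SchemaError`.
    """
    path = Path(path)
    n_header = len(_read_comments(path))
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # unreadable file
        raise SchemaError(str(exc)) from exc
    for col in _ION_REQUIRED + ("map_id", "condition", "platform"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    bad_lines: list[int] = []
    for j, col in enumerate(("mz", "rt_min", "z", "intensity")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if col == "mz":
            bad |= vals <= 0
        elif col == "z":
            bad |= vals < 1
        elif col == "intensity":
            bad |= vals < 0
        bad_lines.extend(df.index[bad].tolist())
        df[col] = vals
    if bad_lines:
        # +2: header row plus 1-based numbering; plus any comment lines
        lines = sorted({i + 2 + n_header for i in bad_lines})
        raise SchemaError(f"invalid rows at line(s) {lines}")
    if "is_internal_standard" not in df.columns:
        df["is_internal_standard"] = False
    for col in ("peptide", "protein"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    maps = []
    for map_id, sub in df.groupby("map_id", sort=True):
        first = sub.iloc[0]
        paired = first.get("paired_map_id", "")
        maps.append(
            IonMap(
                map_id=str(map_id),
                sample_id=str(first.get("sample_id", map_id)),
                condition=str(first["condition"]),
                platform=str(first["platform"]),
                paired_map_id=str(paired) if isinstance(paired, str) and paired else None,
                ions=sub[list(IonMap.ION_COLUMNS)].reset_index(drop=True).astype(
                    {"is_internal_standard": bool}
                ),
            )
        )
    return maps


# ---------------------------------------------------------------------------
# Feature matrices, warps, configs
# ---------------------------------------------------------------------------

def write_feature_matrix(
    fm: FeatureMatrix, path: str | Path, seed: int | None = None, config=None
) -> None:
    merged = fm.meta.join(fm.data).reset_index()
    offsets = [f"# offset {m}: {v!r}" for m, v in fm.offsets.items()]
    write_table(merged, path, seed=seed, config=config, extra_comments=offsets)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    offsets = {}
    for line in _read_comments(path):
        if line.startswith("# offset "):
            body = line[len("# offset "):]
            name, val = body.split(": ")
            offsets[name] = float(val)
    merged = read_table(path).set_index("group_id")
    meta_cols = ["mz", "rt", "z", "n_maps", "peptide", "protein", "is_internal_standard"]
    meta = merged[meta_cols].copy()
    for col in ("peptide", "protein"):
        meta[col] = meta[col].fillna("")
    data = merged.drop(columns=meta_cols)
    data.columns.name = "map_id"
    off = pd.Series(offsets)
    off.index.name = "map_id"
    return FeatureMatrix(data=data, meta=meta, offsets=off)


def warp_to_json(warp: RtWarp) -> str:
    return json.dumps(_to_plain(warp), indent=2)


def warp_from_json(text: str) -> RtWarp:
    d = json.loads(text)
    return RtWarp(
        map_id=d["map_id"],
        kind=d["kind"],
        slope=d.get("slope", 1.0),
        offset=d.get("offset", 0.0),
        knots_obs=None if d.get("knots_obs") is None else np.asarray(d["knots_obs"]),
        knots_ref=None if d.get("knots_ref") is None else np.asarray(d["knots_ref"]),
        anchors=[tuple(a) for a in d.get("anchors", [])],
    )


def write_config(config, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
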