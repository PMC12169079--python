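"""Readers and writers for the pipeline's file formats.

CSV is the canonical tabular interchange (clonotype, cell and transcript
tables); binary masks and zone maps travel as single-channel 8-bit TIFF
(0/255 for masks, zone codes for the zone map) with a JSON legend.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .repertoire import AA_ALPHABET
from .zonation import MaskBundle, Zone, ZoneMap

#: canonical clonotype columns and common aliases accepted without a mapping
_CLONOTYPE_ALIASES = {
    "sample_id": ("sample_id", "sample", "repertoire_id"),
    "v_call": ("v_call", "v_gene", "vGeneName"),
    "j_call": ("j_call", "j_gene", "jGeneName"),
    "junction_aa": ("junction_aa", "cdr3_aa", "aminoAcid", "cdr3aa"),
    "junction": ("junction", "cdr3_nt", "nucleotide"),
    "duplicate_count": ("duplicate_count", "clone_count", "count", "reads", "templates"),
}
_REQUIRED_CLONOTYPE = ("sample_id", "junction_aa", "duplicate_count")


def read_clonotype_table(
    path,
    column_map: dict[str, str] | None = None,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Read a clonotype CSV into canonical AIRR-style columns.

    ``column_map`` maps canonical name -> column name in the file for
    non-AIRR exports; common aliases are recognised without a mapping.
    Lowercase CDR3 sequences are normalised to uppercase with a warning;
    rows with a malformed CDR3 or a non-positive count are rejected with
    their line numbers. ``sample_id`` fills the column when the file lacks
    one.
    """
    raw = pd.read_csv(path)
    rename: dict[str, str] = {}
    for canonical, aliases in _CLONOTYPE_ALIASES.items():
        source = None
        if column_map and canonical in column_map:
            source = column_map[canonical]
            if source not in raw.columns:
                raise ValueError(
                    f"mapped column {source!r} for {canonical!r} not in {path}")
        else:
            source = next((a for a in aliases if a in raw.columns), None)
        if source is not None:
            rename[source] = canonical
    df = raw.rename(columns=rename)
    if "sample_id" not in df.columns:
        if sample_id is None:
            raise ValueError(f"schema error: missing required column 'sample_id' in {path}")
        df["sample_id"] = sample_id
    missing = [c for c in _REQUIRED_CLONOTYPE if c not in df.columns]
    if missing:
        raise ValueError(f"schema error: missing required column(s) {missing} in {path}")

    cdr3 = df["junction_aa"].astype(str)
    lower = cdr3 != cdr3.str.upper()
    if lower.any():
        warnings.warn(
            f"{int(lower.sum())} CDR3 sequences normalised to uppercase in {path}")
        df["junction_aa"] = cdr3.str.upper()

    counts = pd.to_numeric(df["duplicate_count"], errors="coerce")
    bad_count = counts.isna() | (counts < 1)
    bad_cdr3 = df["junction_aa"].map(
        lambda s: not s or not set(s) <= AA_ALPHABET)
    bad = bad_count | bad_cdr3
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        warnings.warn(f"rejected {int(bad.sum())} malformed rows "
                      f"(file lines {lines[:20]}) in {path}")
        df = df[~bad]
    if len(df) == 0:
        raise ValueError(f"no valid clonotype rows in {path}")
    df["duplicate_count"] = pd.to_numeric(df["duplicate_count"]).astype(int)
    keep = [c for c in ("sample_id", "v_call", "j_call", "junction_aa",
                        "junction", "duplicate_count") if c in df.columns]
    return df[keep].reset_index(drop=True)


def write_clonotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as single-channel 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel mask in {path}, got shape {arr.shape}")
    return arr > 0


def write_mask_bundle(masks: MaskBundle, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("hepatocyte", "portal", "sinusoid", "duct"):
        p = outdir / f"{name}.tif"
        write_mask(getattr(masks, name), p)
        paths[name] = str(p)
    (outdir / "pixel_size.json").write_text(
        json.dumps({"pixel_size_um": masks.pixel_size_um}))
    return paths


def read_mask_bundle(indir, pixel_size_um: float | None = None) -> MaskBundle:
    indir = Path(indir)
    if pixel_size_um is None:
        meta = json.loads((indir / "pixel_size.json").read_text())
        pixel_size_um = meta["pixel_size_um"]
    return MaskBundle(
        hepatocyte=read_mask(indir / "hepatocyte.tif"),
        portal=read_mask(indir / "portal.tif"),
        sinusoid=read_mask(indir / "sinusoid.tif"),
        duct=read_mask(indir / "duct.tif"),
        pixel_size_um=pixel_size_um,
    )


def write_zone_map(zone_map: ZoneMap, path, legend_path=None) -> None:
    """Zone map as indexed 8-bit TIFF plus a JSON legend."""
    path = Path(path)
    tifffile.imwrite(path, zone_map.labels.astype(np.uint8))
    legend_path = Path(legend_path) if legend_path else path.with_suffix(".json")
    legend_path.write_text(json.dumps(zone_map.legend(), indent=1))
    if zone_map.duct is not None:
        write_mask(zone_map.duct, path.with_name(path.stem + "_duct.tif"))


def read_zone_map(path, legend_path=None) -> ZoneMap:
    path = Path(path)
    labels = tifffile.imread(path)
    legend_path = Path(legend_path) if legend_path else path.with_suffix(".json")
    legend = json.loads(legend_path.read_text())
    duct_path = path.with_name(path.stem + "_duct.tif")
    duct = read_mask(duct_path) if duct_path.exists() else None
    return ZoneMap(labels=labels.astype(np.uint8),
                   pixel_size_um=float(legend["pixel_size_um"]),
                   band_width_um=float(legend["band_width_um"]),
                   duct=duct)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table {path} missing columns: {sorted(missing)}")
    for col in df.columns:
        if col.startswith("marker_"):
            df[col] = df[col].astype(bool)
    return df


def read_transcript_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"transcript_id", "feature_name", "x_um", "y_um", "cell_id", "qv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table {path} missing columns: {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if np.isnan(o) else float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, tuple)):
            return list(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))
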