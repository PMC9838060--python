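"""Readers, writers and validation for every file the pipeline touches.

Formats: multi-page TIFF per field (page order channel-major, then Z, channel
names in the page metadata), plain CSV/TSV tables (UTF-8, header row), FASTQ
with Phred+33 qualities, YAML/JSON configuration, and a ``manifest.json``
tying a run's outputs together.  All writers are deterministic given
identical inputs.
"""

from __future__ import annotations

import json
import re
from collections import namedtuple
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .errors import FormatError, LayoutError
from .hci import CellRecord, ChannelStack, WellSummary

CONTROL_ROLES = ("none", "no_guide_control", "reporter_only")

FastqRead = namedtuple("FastqRead", ["id", "seq", "qual"])

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


# ---------------------------------------------------------------------------
# well naming
# ---------------------------------------------------------------------------


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate well name, e.g. (1, 6) -> 'B7'."""
    return f"{chr(ord('A') + row)}{col + 1}"


def parse_well(name: str, plate_shape: tuple[int, int] = (8, 12)) -> tuple[int, int]:
    """Well name -> 0-based (row, col); validates against the plate shape."""
    m = _WELL_RE.match(name.strip())
    if not m:
        raise LayoutError(f"malformed well id {name!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if row >= plate_shape[0] or col >= plate_shape[1] or col < 0:
        raise LayoutError(f"well {name!r} outside plate shape {plate_shape}")
    return row, col


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ["well", "condition", "replicate_group", "control_role", "species_mode"]


def validate_layout(layout: pd.DataFrame, plate_shape: tuple[int, int] = (8, 12)) -> pd.DataFrame:
    """Validate a layout table: unique wells within the plate, known roles."""
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise LayoutError(f"layout missing columns: {missing}")
    dupes = layout["well"][layout["well"].duplicated()].tolist()
    if dupes:
        raise LayoutError(f"duplicated wells in layout: {sorted(set(dupes))}")
    for i, well in enumerate(layout["well"]):
        try:
            parse_well(str(well), plate_shape)
        except LayoutError as exc:
            raise LayoutError(f"layout row {i + 2}: {exc}") from None  # +2: header + 1-based
    bad = set(layout["control_role"]) - set(CONTROL_ROLES)
    if bad:
        raise LayoutError(f"unknown control_role values: {sorted(bad)}")
    return layout


def read_layout(path: str | Path, plate_shape: tuple[int, int] = (8, 12)) -> pd.DataFrame:
    layout = pd.read_csv(path, dtype=str).fillna("")
    layout["control_role"] = layout["control_role"].replace("", "none")
    return validate_layout(layout, plate_shape)


def write_layout(layout: pd.DataFrame, path: str | Path) -> None:
    validate_layout(layout)
    layout.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write one field as a multi-page TIFF, channel-major then Z."""
    channel_names = list(stack.channels)
    pages = np.concatenate([stack.channels[c] for c in channel_names], axis=0)
    meta = {
        "well": stack.well,
        "field": stack.field,
        "channels": channel_names,
        "z_planes": int(next(iter(stack.channels.values())).shape[0]),
        "pixel_size_um": stack.pixel_size_um,
    }
    tifffile.imwrite(str(path), pages.astype(np.uint16), photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path: str | Path) -> ChannelStack:
    """Read a field TIFF back into a ChannelStack (lossless round trip)."""
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        channel_names = meta["channels"]
        z = int(meta["z_planes"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed stack metadata") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != len(channel_names) * z:
        raise FormatError(
            f"{path}: {pages.shape[0]} pages do not match "
            f"{len(channel_names)} channels x {z} Z planes"
        )
    channels = {
        name: pages[i * z : (i + 1) * z] for i, name in enumerate(channel_names)
    }
    return ChannelStack(
        well=meta.get("well", ""),
        field=int(meta.get("field", 0)),
        channels=channels,
        pixel_size_um=meta.get("pixel_size_um"),
    )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path):
    """Iterate FASTQ records as (id, seq, qual) with Phred+33 qualities.

    Malformed records raise FormatError naming the failing record index.
    """
    index = 0
    parser = SeqIO.parse(str(path), "fastq")
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"{path}: FASTQ record {index}: {exc}") from exc
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield FastqRead(rec.id, str(rec.seq), qual)
        index += 1


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for read in reads:
            if len(read.seq) != len(read.qual):
                raise FormatError(
                    f"record {read.id!r}: sequence and quality lengths differ"
                )
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def _with_rounded(df: pd.DataFrame) -> pd.DataFrame:
    """Emit every *_pct column both raw and rounded to one decimal."""
    out = df.copy()
    for col in list(out.columns):
        if col.endswith("_pct"):
            out[col + "_1dp"] = out[col].round(1)
    return out


def records_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "well": r.well,
                "field": r.field,
                "label": r.label,
                "centroid_y": r.centroid[0],
                "centroid_x": r.centroid[1],
                "area_px2": r.area,
                "roundness": r.roundness,
                "has_nucleus": r.has_nucleus,
                "mean_nuclear_mcherry": r.mean_nuclear_mcherry,
                "mean_nuclear_gfp": r.mean_nuclear_gfp,
                "is_protoplast": r.is_protoplast,
                "is_transfected": r.is_transfected,
                "is_gfp_positive": r.is_gfp_positive,
                "gfp_above_threshold": r.gfp_above_threshold,
            }
        )
    return pd.DataFrame(rows)


def summaries_frame(summaries: list[WellSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "well": s.well,
                "condition": s.condition,
                "control": s.control,
                "n_cells": s.n_cells,
                "n_transfected": s.n_transfected,
                "n_gfp_positive": s.n_gfp_positive,
                "n_gfp_independent": s.n_gfp_independent,
                "mean_gfp_transfected": s.mean_gfp_transfected,
            }
        )
    return pd.DataFrame(rows).sort_values("well").reset_index(drop=True)


def summaries_from_frame(df: pd.DataFrame) -> list[WellSummary]:
    out = []
    for row in df.itertuples():
        out.append(
            WellSummary(
                well=str(row.well),
                n_cells=int(row.n_cells),
                n_transfected=int(row.n_transfected),
                n_gfp_positive=int(row.n_gfp_positive),
                mean_gfp_transfected=float(getattr(row, "mean_gfp_transfected", float("nan"))),
                n_gfp_independent=int(getattr(row, "n_gfp_independent", 0)),
                condition=str(getattr(row, "condition", "")),
                control=bool(getattr(row, "control", False)),
            )
        )
    return out


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> Path:
    """Write result tables as CSV plus a manifest.json; returns manifest path.

    Row order is preserved as given, so identical inputs produce identical
    files.  Percentage columns (``*_pct``) are emitted both raw and rounded to
    one decimal.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"tables": {}}
    for name in sorted(tables):
        path = outdir / f"{name}.csv"
        _with_rounded(tables[name]).to_csv(path, index=False)
        manifest["tables"][name] = path.name
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
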