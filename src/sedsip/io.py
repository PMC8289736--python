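"""File formats: abundance-table TSV, ion-stack TIFF + JSON manifests, results.

Canonical dialects: tab-separated tables with '.' decimal separator and
UTF-8 encoding; multi-page TIFF per ion species (pages = planes, unsigned
integer for raw counts, 32-bit float for at% maps); JSON for stack and run
manifests; YAML for generator configurations.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .gradient import AbundanceTable, DetectionResult, META_COLUMNS
from .nanosims import CellIsotopeResult, ControlReference, IonCountStack, IsotopeMap, RoiSet


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          meta_path: str | Path) -> None:
    """Write the ASV x sample matrix and its sample metadata as TSV."""
    df = table.data.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")
    meta = table.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_abundance_table(path: str | Path, meta_path: str | Path,
                         mode: str = "counts") -> AbundanceTable:
    """Read an abundance TSV plus sample-metadata TSV into a typed table."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    if data.index.has_duplicates:
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ASV ids: {dupes}")
    if data.columns.has_duplicates:
        raise ValueError("duplicate sample ids in table header")
    try:
        values = data.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance value: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"replicate": str})
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks column(s): {missing_cols}")
    unmatched = [s for s in values.columns if s not in meta.index]
    if unmatched:
        raise ValueError(f"samples without metadata: {unmatched}")
    meta = meta.loc[list(values.columns)].copy()
    meta["timepoint_days"] = meta["timepoint_days"].astype(int)
    meta["density"] = meta["density"].astype(float)
    table = AbundanceTable(data=values, meta=meta, mode=mode)
    if mode == "relative":
        table.validate_relative()
    return table


# ---------------------------------------------------------------------------
# ion-count stacks
# ---------------------------------------------------------------------------


def write_ion_stack(stack: IonCountStack, out_dir: str | Path,
                    prefix: str = "stack") -> Path:
    """Write one multi-page TIFF per species plus a JSON manifest.

    Raw stacks are written as unsigned integers, corrected stacks as
    32-bit floats.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for sp, arr in stack.counts.items():
        fname = f"{prefix}_{sp}.tif"
        if stack.corrected:
            data = np.asarray(arr, dtype=np.float32)
        else:
            data = np.asarray(np.round(arr), dtype=np.uint32)
        tifffile.imwrite(out_dir / fname, data, photometric="minisblack")
        files[sp] = fname
    manifest = {
        "species_files": files,
        "dwell_time_s": stack.dwell_time_s,
        "dead_time_s": stack.dead_time_s,
        "field_size_um": stack.field_size_um,
        "corrected": stack.corrected,
    }
    manifest_path = out_dir / f"{prefix}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_ion_stack(manifest_path: str | Path) -> IonCountStack:
    """Read a stack from its JSON manifest (species -> TIFF mapping)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    counts: dict[str, np.ndarray] = {}
    corrected = bool(manifest.get("corrected", False))
    for sp, fname in manifest["species_files"].items():
        arr = tifffile.imread(base / fname)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if not corrected:
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(
                    f"species {sp}: raw stack must be integer-valued, got {arr.dtype}"
                )
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(float)
        counts[sp] = arr
    planes = {sp: a.shape[0] for sp, a in counts.items()}
    if len(set(planes.values())) != 1:
        raise ValueError(f"species have inconsistent plane counts: {planes}")
    return IonCountStack(
        counts=counts,
        dwell_time_s=float(manifest["dwell_time_s"]),
        dead_time_s=float(manifest["dead_time_s"]),
        field_size_um=float(manifest.get("field_size_um", 60.0)),
        corrected=corrected,
    )


def write_roi_labels(rois: RoiSet, path: str | Path) -> None:
    tifffile.imwrite(Path(path), rois.labels.astype(np.uint16))


def read_roi_labels(path: str | Path, min_pixels: int = 10) -> RoiSet:
    labels = tifffile.imread(Path(path)).astype(np.int32)
    return RoiSet(labels=labels, min_pixels=min_pixels, provenance="file")


def write_isotope_map(iso: IsotopeMap, path: str | Path) -> None:
    """at% map as 32-bit float TIFF; invalid pixels carry NaN."""
    img = np.where(iso.valid, iso.atpct, np.nan).astype(np.float32)
    tifffile.imwrite(Path(path), img)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------


def write_detection_results(result: DetectionResult, out_dir: str | Path,
                            prefix: str = "detection") -> tuple[Path, Path]:
    """LabelSummary and LabelCall audit tables as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_path = out_dir / f"{prefix}_summary.tsv"
    calls_path = out_dir / f"{prefix}_calls.tsv"
    result.summaries_frame().to_csv(summary_path, sep="\t", index=False)
    result.calls_frame().to_csv(calls_path, sep="\t", index=False)
    return summary_path, calls_path


def write_cell_results(cells: Sequence[CellIsotopeResult], path: str | Path,
                       control: ControlReference | None = None) -> None:
    rows = [asdict(c) for c in cells]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    if control is not None:
        ctrl_path = Path(path).with_suffix(".control.json")
        ctrl_path.write_text(json.dumps(asdict(control), indent=2))


def read_control_cells(path: str | Path, column: str = "atpct") -> list[float]:
    """Read per-cell at% values of a control population from a TSV."""
    df = pd.read_csv(path, sep="\t")
    if column not in df.columns:
        raise ValueError(f"control table lacks column {column!r}")
    return [float(v) for v in df[column]]


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted alongside every command's outputs."""

    command: str
    parameters: dict
    seed: int | None = None
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    @classmethod
    def create(cls, command: str, parameters: Mapping, seed: int | None = None,
               inputs: Sequence[str | Path] = ()) -> "RunManifest":
        digests = {str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()}
        return cls(command=command, parameters=dict(parameters), seed=seed,
                   input_digests=digests)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
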