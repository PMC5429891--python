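"""File formats: label-image stacks (TIFF + sidecar), count sheets, estimates.

Conventions: geometry in micrometres, sections 0-indexed from the stack start,
slab interval [offset, offset + h_phys) half-open.  The metadata sidecar
(JSON or YAML) must give at least the pixel size and section spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .estimators import Estimate
from .probes import CountRecord

__all__ = [
    "StackMetadata",
    "read_label_stack",
    "write_label_stack",
    "read_counts_csv",
    "write_counts_csv",
    "write_estimates_csv",
    "write_estimates_json",
]

_REQUIRED = ("pixel_size", "spacing_k")


@dataclass
class StackMetadata:
    pixel_size: float  # um
    spacing_k: float  # um between sections
    h_phys: float = 0.0
    h_img: float = 0.0
    orientation_mode: str = "arbitrary"  # arbitrary | iur | vertical
    horizontal_axis: Optional[list] = None  # for vertical mode
    labels: dict = field(default_factory=dict)  # int -> structure class

    def __post_init__(self):
        if self.pixel_size <= 0 or self.spacing_k <= 0:
            raise ValueError("pixel size and section spacing must be positive")
        self.labels = {int(k): v for k, v in self.labels.items()}
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("label dictionary must be one-to-one")

    @classmethod
    def from_file(cls, path) -> "StackMetadata":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        missing = [k for k in _REQUIRED if k not in data]
        if missing:
            raise KeyError(f"metadata sidecar missing required field(s): {missing}")
        return cls(**data)

    def to_file(self, path):
        path = Path(path)
        data = {
            "pixel_size": self.pixel_size,
            "spacing_k": self.spacing_k,
            "h_phys": self.h_phys,
            "h_img": self.h_img,
            "orientation_mode": self.orientation_mode,
            "horizontal_axis": self.horizontal_axis,
            "labels": {str(k): v for k, v in self.labels.items()},
        }
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(data, fh)
            else:
                json.dump(data, fh, indent=1)


def read_label_stack(path, metadata) -> tuple[list[np.ndarray], StackMetadata]:
    """Multipage integer-label TIFF plus its metadata sidecar."""
    if not isinstance(metadata, StackMetadata):
        metadata = StackMetadata.from_file(metadata)
    with tifffile.TiffFile(path) as tf:
        pages = [page.asarray() for page in tf.pages]
    for i, img in enumerate(pages):
        if not np.issubdtype(img.dtype, np.integer):
            raise TypeError(f"page {i} is not an integer label image ({img.dtype})")
    return pages, metadata


def write_label_stack(path, images, metadata: StackMetadata, sidecar=None):
    arr = np.stack([np.asarray(im) for im in images])
    tifffile.imwrite(path, arr, photometric="minisblack")
    if sidecar is not None:
        metadata.to_file(sidecar)


def sur_subsample(n_pages: int, n_used: int, seed=None) -> list[int]:
    """SUR selection of ``n_used`` of ``n_pages`` sections (random phase)."""
    from .phantom import as_rng

    spacing = n_pages // n_used
    if spacing < 1:
        raise ValueError("cannot use more sections than exist")
    start = int(as_rng(seed).integers(0, spacing))
    return list(range(start, n_pages, spacing))[:n_used]


# ---------------------------------------------------------------------------
# count sheets
# ---------------------------------------------------------------------------

_COUNT_COLS = ("image_id", "label", "P", "I", "Qminus")


def read_counts_csv(path) -> list[CountRecord]:
    """Manual count sheet: columns image_id, label, P, I, Qminus[, l0].

    ``l0`` holds point-sampled intercept lengths as a semicolon-separated
    list in micrometres.  Rows are validated: counts must be non-negative and
    (image_id, label) pairs unique.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise KeyError(f"count sheet missing column(s): {missing}")
    dup = df.duplicated(subset=["image_id", "label"])
    if dup.any():
        raise ValueError(f"duplicate (image_id, label) at row {int(dup.idxmax()) + 2}")
    records = []
    for idx, row in df.iterrows():
        try:
            intercepts = []
            if "l0" in df.columns and isinstance(row.get("l0"), str) and row["l0"].strip():
                intercepts = [float(v) for v in row["l0"].split(";")]
            rec = CountRecord(
                image_id=int(row["image_id"]),
                label=str(row["label"]),
                P=int(row["P"]),
                I=int(row["I"]),
                Qminus=int(row["Qminus"]),
                intercepts=intercepts,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed count sheet row {idx + 2}: {exc}") from exc
        records.append(rec)
    return records


def write_counts_csv(path, records: list[CountRecord]):
    rows = []
    for r in records:
        rows.append({
            "image_id": r.image_id,
            "label": r.label,
            "P": r.P,
            "I": r.I,
            "Qminus": r.Qminus,
            "l0": ";".join(f"{v:.6g}" for v in r.intercepts),
        })
    pd.DataFrame(rows, columns=list(_COUNT_COLS) + ["l0"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------


def write_estimates_csv(path, estimates: list[Estimate], seed=None, config_hash=None):
    rows = [e.to_row() for e in estimates]
    for row in rows:
        row["seed"] = seed
        row["config_hash"] = config_hash
    pd.DataFrame(rows).to_csv(path, index=False)


def write_estimates_json(path, estimates: list[Estimate], seed=None, config_hash=None):
    payload = {
        "seed": seed,
        "config_hash": config_hash,
        "estimates": [dict(e.to_row(), extra=e.extra) for e in estimates],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
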