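"""Reading and writing of volumes, masks and tables.

Multi-channel volumes go to OME-TIFF with channel names in the metadata
(and an adjacent JSON sidecar naming the channel order, which the
reader relies on); label volumes to 16-bit single-channel TIFF; region
masks to 8-bit TIFF; tables to CSV with a fixed float format so reruns
are byte-identical.
"""

from __future__ import annotations

import json
import uuid
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

FLOAT_FORMAT = "%.6g"


def write_channels(path: Path, channels: dict[str, np.ndarray]) -> None:
    """Write a named multi-channel volume as OME-TIFF plus sidecar."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([channels[n].astype(np.float32) for n in names], axis=0)
    # content-derived UUID keeps repeated writes byte-identical
    stable_uuid = uuid.uuid5(uuid.NAMESPACE_URL, "perimac:" + ",".join(names))
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "UUID": f"urn:uuid:{stable_uuid}",
        },
    )
    path.with_suffix(".json").write_text(
        json.dumps({"channels": names}, indent=2)
    )


def read_channels(path: Path) -> dict[str, np.ndarray]:
    path = Path(path)
    names = json.loads(path.with_suffix(".json").read_text())["channels"]
    stack = tifffile.imread(path)
    if stack.ndim == 3:  # single channel collapsed
        stack = stack[None]
    return {n: stack[i].astype(np.float64) for i, n in enumerate(names)}


def write_labels(path: Path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit volume")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_mask(path: Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def read_mask(path: Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(bool)


def write_table(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


def write_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def read_json(path: Path):
    return json.loads(Path(path).read_text())
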