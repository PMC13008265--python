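"""Reading and writing the pipeline's artifacts (TIFF, CSV, JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import LabeledMask


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_mask(path: str | Path, mask: LabeledMask) -> None:
    """Label mask as 16-bit TIFF plus a JSON provenance sidecar."""
    path = Path(path)
    labels = mask.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit")
    tifffile.imwrite(str(path), labels.astype(np.uint16))
    sidecar = dict(
        pixel_size=mask.pixel_size, channel=mask.channel, provenance=mask.provenance
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def read_mask(path: str | Path) -> LabeledMask:
    path = Path(path)
    labels = tifffile.imread(str(path)).astype(np.int32)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return LabeledMask(
        labels=labels,
        pixel_size=float(sidecar["pixel_size"]),
        channel=sidecar.get("channel", "cell"),
        provenance=sidecar.get("provenance", {}),
    )


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path))
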