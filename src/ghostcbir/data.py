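"""Dataset directory I/O: 8-bit grayscale PNG slices + a delimited metadata
table (image_id, patient_id, label, path)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .protocol import SliceRecord

__all__ = ["save_dataset", "load_dataset"]

METADATA_NAME = "metadata.csv"


def save_dataset(records: list[SliceRecord], directory) -> Path:
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rel = f"images/{rec.image_id}.png"
        Image.fromarray(np.asarray(rec.pixels, dtype=np.uint8), mode="L").save(
            directory / rel)
        rows.append({"image_id": rec.image_id, "patient_id": rec.patient_id,
                     "label": rec.label, "path": rel})
    table = directory / METADATA_NAME
    pd.DataFrame(rows).to_csv(table, index=False)
    return table


def load_dataset(directory) -> list[SliceRecord]:
    directory = Path(directory)
    meta = pd.read_csv(directory / METADATA_NAME)
    records = []
    for row in meta.itertuples(index=False):
        pixels = np.asarray(Image.open(directory / row.path).convert("L"))
        records.append(SliceRecord(image_id=str(row.image_id),
                                   patient_id=str(row.patient_id),
                                   label=row.label, pixels=pixels))
    return records
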