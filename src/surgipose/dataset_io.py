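"""Load generated dataset directories back into in-memory samples."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image

from .geometry import load_instrument_model, load_intrinsics, load_pose
from .labels import Keypoints2D, load_mask, load_vector_field
from .simulator import Sample

__all__ = ["load_dataset_samples"]


def load_dataset_samples(dataset_dir: str | Path) -> Iterator[Sample]:
    """Yield one ``Sample`` per manifest line of a dataset directory."""
    root = Path(dataset_dir)
    K = load_intrinsics(root / "intrinsics.json")
    model = load_instrument_model(root / "model.ply")
    for line in (root / "manifest.jsonl").read_text().splitlines():
        rec = json.loads(line)
        image = np.asarray(Image.open(root / rec["image"]).convert("RGB"))
        seg = load_mask(root / rec["mask"])
        vfield = load_vector_field(root / rec["vfield"]).astype(np.float32)
        pose = load_pose(root / rec["pose"])
        kp_xy = np.asarray(rec["keypoints2d"], dtype=float)
        visible = (
            np.isfinite(kp_xy).all(axis=1)
            & (kp_xy[:, 0] >= -0.5)
            & (kp_xy[:, 0] <= K.width - 0.5)
            & (kp_xy[:, 1] >= -0.5)
            & (kp_xy[:, 1] <= K.height - 0.5)
        )
        yield Sample(
            image=image,
            seg=seg,
            vfield=vfield,
            keypoints2d=Keypoints2D(xy=kp_xy, visible=visible),
            pose=pose,
            intrinsics=K,
            keypoints3d=model.keypoints3d.copy(),
            meta={
                "frame_id": rec["frame"],
                "light": rec.get("light"),
                "occluder": rec.get("occluder"),
            },
        )
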