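"""File I/O for the standard interchange formats.

Video and channel stacks travel as multi-page TIFF, pressure traces and
per-cycle/per-cell tables as CSV, schedules and trains as JSON, and
simulation configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .behavior import BlockSchedule, FrameStack
from .stimulation import StimulusTrain
from .synthetic.fish import ChannelStack

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_channel_stack",
    "read_channel_stack",
    "write_schedule",
    "read_schedule",
    "write_train",
    "read_train",
    "load_yaml_config",
]


def write_frame_stack(path: str | Path, stack: FrameStack) -> None:
    tifffile.imwrite(
        path,
        stack.frames,
        metadata={"frame_rate_hz": stack.frame_rate_hz, "px_per_cm": stack.px_per_cm},
    )


def read_frame_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    px_per_cm: float | None = None,
) -> FrameStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return FrameStack(
        frames,
        frame_rate_hz=frame_rate_hz or float(meta.get("frame_rate_hz", 60.0)),
        px_per_cm=px_per_cm or float(meta.get("px_per_cm", 1.0)),
    )


def write_channel_stack(path: str | Path, stack: ChannelStack) -> None:
    tifffile.imwrite(
        path,
        stack.as_array().astype(np.float32),
        metadata={"px_per_um": stack.px_per_um, "channels": ["DAPI", "Cy5", "Cy3"]},
    )


def read_channel_stack(path: str | Path, px_per_um: float | None = None) -> ChannelStack:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if arr.shape[0] != 3:
        raise ValueError("expected a 3-channel stack (DAPI, Cy5, Cy3)")
    return ChannelStack(
        dapi=arr[0].astype(float),
        cy5=arr[1].astype(float),
        cy3=arr[2].astype(float),
        px_per_um=px_per_um or float(meta.get("px_per_um", 1.0)),
    )


def write_schedule(path: str | Path, schedule: BlockSchedule) -> None:
    with open(path, "w") as fh:
        json.dump(schedule.to_dict(), fh, indent=2)


def read_schedule(path: str | Path) -> BlockSchedule:
    with open(path) as fh:
        return BlockSchedule.from_dict(json.load(fh))


def write_train(path: str | Path, train: StimulusTrain) -> None:
    Path(path).write_text(train.to_json())


def read_train(path: str | Path) -> StimulusTrain:
    return StimulusTrain.from_json(Path(path).read_text())


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
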