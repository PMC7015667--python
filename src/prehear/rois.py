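"""Region-of-interest geometry.

ROIs are named 2-D regions (rectangles, ellipses, or polygons, in pixel
coordinates) tagged with a cochlear/midbrain compartment label.  They are
serialized as a simple JSON geometry file and rasterized to boolean masks
on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

__all__ = ["ROI", "ROISet"]

COMPARTMENTS = {"ISC", "IHC", "SGN", "whole_field", "left", "right", "other"}


@dataclass(frozen=True)
class ROI:
    """One named region; ``shape`` is rect, ellipse, or polygon.

    rect params: x, y, w, h (x=col, y=row of the top-left corner)
    ellipse params: cx, cy, rx, ry
    polygon params: vertices [[x, y], ...]
    """

    name: str
    shape: str
    params: dict
    compartment: str = "other"

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        h, w = image_shape
        m = np.zeros((h, w), dtype=bool)
        if self.shape == "rect":
            x, y = self.params["x"], self.params["y"]
            rw, rh = self.params["w"], self.params["h"]
            m[int(y) : int(y + rh), int(x) : int(x + rw)] = True
        elif self.shape == "ellipse":
            rr, cc = skdraw.ellipse(
                self.params["cy"], self.params["cx"],
                self.params["ry"], self.params["rx"], shape=(h, w),
            )
            m[rr, cc] = True
        elif self.shape == "polygon":
            verts = np.asarray(self.params["vertices"], dtype=float)
            rr, cc = skdraw.polygon(verts[:, 1], verts[:, 0], shape=(h, w))
            m[rr, cc] = True
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        return m

    @property
    def centroid_px(self) -> tuple[float, float]:
        """(col, row) centroid from the geometry parameters."""
        if self.shape == "rect":
            return (
                self.params["x"] + self.params["w"] / 2.0,
                self.params["y"] + self.params["h"] / 2.0,
            )
        if self.shape == "ellipse":
            return (float(self.params["cx"]), float(self.params["cy"]))
        verts = np.asarray(self.params["vertices"], dtype=float)
        return (float(verts[:, 0].mean()), float(verts[:, 1].mean()))

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the geometry."""
        if self.shape == "rect":
            x, y = self.params["x"], self.params["y"]
            return x, y, x + self.params["w"], y + self.params["h"]
        if self.shape == "ellipse":
            cx, cy, rx, ry = (self.params[k] for k in ("cx", "cy", "rx", "ry"))
            return cx - rx, cy - ry, cx + rx, cy + ry
        verts = np.asarray(self.params["vertices"], dtype=float)
        return (
            verts[:, 0].min(), verts[:, 1].min(),
            verts[:, 0].max(), verts[:, 1].max(),
        )


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_compartment(self, compartment: str) -> list[ROI]:
        return [r for r in self.rois if r.compartment == compartment]

    def validate(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        for r in self.rois:
            xmin, ymin, xmax, ymax = r.bounds()
            if xmin < 0 or ymin < 0 or xmax > w or ymax > h:
                raise ValueError(f"ROI {r.name!r} extends outside the {h}x{w} image")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rois": [
                {
                    "name": r.name,
                    "shape": r.shape,
                    "params": r.params,
                    "compartment": r.compartment,
                }
                for r in self.rois
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(
        cls, path: str | Path, image_shape: tuple[int, int] | None = None
    ) -> "ROISet":
        payload = json.loads(Path(path).read_text())
        rois = [
            ROI(d["name"], d["shape"], d["params"], d.get("compartment", "other"))
            for d in payload["rois"]
        ]
        rs = cls(rois)
        if image_shape is not None:
            rs.validate(image_shape)
        return rs
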