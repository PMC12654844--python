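"""Plate-image registration: template building, corner/fiducial detection and
realignment of every frame onto the reference (final-timepoint) grid.

Four corner correspondences determine a plane-projective transform exactly;
that homography (downgraded to affine/identity when the fitted matrix lies in
those subfamilies) realigns each earlier photograph onto the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, transform
from skimage.filters import threshold_otsu

from spotlag.experiment_model import DesignError, DropSpec, PlateLayout

#: luminance weights for RGB -> grayscale conversion
_LUMA = np.array([0.2126, 0.7152, 0.0722])


class RegistrationError(RuntimeError):
    """Corner detection or transform estimation failed."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to single-channel luminance; pass 2-D through."""
    if image.ndim == 2:
        return np.asarray(image, dtype=float)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return np.asarray(image[..., :3], dtype=float) @ _LUMA
    raise ValueError(f"unsupported image shape {image.shape}")


@dataclass
class PlateImageSeries:
    """Ordered time-stamped frames of one plate; the last frame is the reference."""

    plate_id: str
    frames: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a series needs at least one frame")
        days = [d for d, _ in self.frames]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("frame days must be strictly increasing")

    @property
    def days(self) -> list[float]:
        return [d for d, _ in self.frames]

    @property
    def reference_index(self) -> int:
        return len(self.frames) - 1

    @property
    def reference_image(self) -> np.ndarray:
        return self.frames[-1][1]


@dataclass(frozen=True)
class PlaneTransform:
    """3x3 homogeneous plane transform, normalised so matrix[2, 2] == 1.

    Maps (x, y) source-pixel coordinates to template coordinates.
    ``kind`` records the smallest subfamily the matrix belongs to.
    """

    matrix: np.ndarray
    kind: str = field(default="projective")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if abs(m[2, 2]) < 1e-12 or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("transform matrix must be invertible")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        out = homo @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "PlaneTransform":
        return PlaneTransform(np.linalg.inv(self.matrix))


def _classify(matrix: np.ndarray, tol: float = 1e-8) -> str:
    if np.max(np.abs(matrix[2, :2])) > tol:
        return "projective"
    if np.max(np.abs(matrix - np.eye(3))) <= tol:
        return "identity"
    return "affine"


def estimate_transform(
    source_corners, template_corners, corner_tol: float = 0.5
) -> PlaneTransform:
    """Exact projective map taking the 4 source corners onto the 4 template corners.

    Both corner lists must be ordered the same way (clockwise from top-left).
    Raises :class:`RegistrationError` on degenerate (collinear) corners or if
    the fitted map leaves a corner residual above ``corner_tol`` pixels.
    """
    src = np.asarray(source_corners, dtype=float)
    dst = np.asarray(template_corners, dtype=float)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise ValueError("corner sets must each contain 4 (x, y) pairs")
    for pts in (src, dst):
        # degenerate if any 3 of the 4 points are collinear
        for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            a, b, c = pts[list(idx)]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if abs(cross) < 1e-9:
                raise RegistrationError("collinear corners: homography undefined")
    tf = transform.ProjectiveTransform.from_estimate(src, dst)
    if not tf:
        raise RegistrationError("homography estimation failed")
    pt = PlaneTransform(tf.params)
    residual = np.max(np.linalg.norm(pt.apply_points(src) - dst, axis=1))
    if residual > corner_tol:
        raise RegistrationError(f"corner residual {residual:.3g} px > {corner_tol}")
    return PlaneTransform(pt.matrix, kind=_classify(pt.matrix))


def apply_transform(image: np.ndarray, t: PlaneTransform) -> np.ndarray:
    """Resample ``image`` onto the template grid through ``t``.

    Bilinear interpolation; pixels pulled from outside the source frame are
    set to the background value 0.
    """
    gray = to_grayscale(image)
    if np.max(np.abs(t.matrix - np.eye(3))) <= 1e-12:
        return gray.copy()
    # warp() wants the map from output (template) coords to input coords
    inv = transform.ProjectiveTransform(matrix=np.linalg.inv(t.matrix))
    return transform.warp(
        gray, inverse_map=inv, order=1, cval=0.0, mode="constant", preserve_range=True
    )


def build_template(
    reference_image: np.ndarray,
    drop_coordinates,
    corner_coordinates,
    *,
    plate_id: str = "plate",
    roi_radius: float = 40.0,
    drop_metadata: list[dict] | None = None,
) -> PlateLayout:
    """Define the drop-position template on the reference frame's pixel grid.

    ``drop_metadata`` optionally carries per-drop assay fields (strain, dose,
    density_class, ...) merged into each :class:`DropSpec`.
    """
    gray = to_grayscale(reference_image)
    h, w = gray.shape
    corners = [tuple(float(v) for v in c) for c in corner_coordinates]
    for x, y in list(drop_coordinates) + corners:
        if not (0 <= x < w and 0 <= y < h):
            raise DesignError(f"coordinate ({x}, {y}) outside image bounds {w}x{h}")
    drops = []
    for i, center in enumerate(drop_coordinates):
        meta = dict(drop_metadata[i]) if drop_metadata else {}
        meta.setdefault("drop_id", f"d{i:03d}")
        meta.setdefault("strain", "unknown")
        drops.append(
            DropSpec(
                center=tuple(float(v) for v in center),
                roi_radius=float(roi_radius),
                **meta,
            )
        )
    return PlateLayout(
        plate_id=plate_id, width_px=w, height_px=h, corners=corners, drops=drops
    )


def detect_corners(
    image: np.ndarray,
    *,
    window_frac: float = 0.12,
    config_corners=None,
) -> list[tuple[float, float]]:
    """Locate the 4 corner fiducial marks, clockwise from top-left.

    Each image quadrant's outermost window is thresholded (Otsu) and the
    centroid of the *brightest* blob (highest mean intensity, area >= 10 px)
    taken as the fiducial centre -- fiducial marks are brighter than both
    agar and colonies, so a colony straying into the window is ignored.
    ``config_corners``, when given, bypasses detection entirely (the manual
    entry path for real photographs without fiducials).
    """
    if config_corners is not None:
        return [tuple(float(v) for v in c) for c in config_corners]
    gray = to_grayscale(image)
    h, w = gray.shape
    wy, wx = max(16, int(h * window_frac)), max(16, int(w * window_frac))
    windows = {
        "tl": (slice(0, wy), slice(0, wx)),
        "tr": (slice(0, wy), slice(w - wx, w)),
        "br": (slice(h - wy, h), slice(w - wx, w)),
        "bl": (slice(h - wy, h), slice(0, wx)),
    }
    found: dict[str, tuple[float, float]] = {}
    for name, (sy, sx) in windows.items():
        win = gray[sy, sx]
        if win.max() - win.min() < 0.05:
            continue  # featureless window: no fiducial here
        mask = win > threshold_otsu(win)
        labels = measure.label(mask)
        props = [
            p
            for p in measure.regionprops(labels, intensity_image=win)
            if p.area >= 10
        ]
        if not props:
            continue
        blob = max(props, key=lambda p: p.intensity_mean)
        cy, cx = blob.centroid_weighted
        found[name] = (float(cx + sx.start), float(cy + sy.start))
    if len(found) < 4:
        raise RegistrationError(
            f"only {len(found)}/4 fiducial marks found; supply corners manually"
        )
    return [found["tl"], found["tr"], found["br"], found["bl"]]


def register_series(
    series: PlateImageSeries,
    template_corners=None,
    *,
    per_frame_corners: list | None = None,
) -> tuple[PlateImageSeries, list[PlaneTransform]]:
    """Realign every frame of a series onto the reference frame's grid.

    Corners are detected per frame (or supplied via ``per_frame_corners``);
    the reference frame's corners define the template.  Returns the
    registered series and the per-frame transforms.  Drop identity and
    metadata are untouched: registration only resamples pixels.
    """
    if template_corners is None:
        template_corners = detect_corners(series.reference_image)
    registered: list[tuple[float, np.ndarray]] = []
    transforms: list[PlaneTransform] = []
    for i, (day, img) in enumerate(series.frames):
        if per_frame_corners is not None:
            corners = per_frame_corners[i]
        else:
            corners = detect_corners(img)
        t = estimate_transform(corners, template_corners)
        registered.append((day, apply_transform(img, t)))
        transforms.append(t)
    return PlateImageSeries(series.plate_id, registered), transforms
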