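"""Thin-plate-spline transformation between homologous 2-D landmark sets.

The classical 2-D thin-plate spline: the map minimizing bending energy
subject to interpolating the landmark pairs, with radial kernel
U(r) = r^2 log r^2 (U(0) = 0) plus an affine part.  With zero
regularization the fit interpolates the landmarks exactly; a positive
regularization yields a smoothing spline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist, pdist

__all__ = ["TPSTransform", "fit_tps", "map_points", "warp_image",
           "invert_fit", "save_transform", "load_transform"]

_INTERP_ORDER = {"nearest": 0, "linear": 1, "cubic": 3}


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 evaluated from squared distances; U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TPSTransform:
    """A fitted thin-plate-spline map from source to target coordinates.

    Attributes
    ----------
    control_points : (n, 2) ndarray
        Source landmark coordinates.
    weights : (n, 2) ndarray
        Kernel coefficients, one column per output dimension.
    affine : (3, 2) ndarray
        Affine coefficients [1, x, y] -> output, one column per dimension.
    """

    control_points: np.ndarray
    weights: np.ndarray
    affine: np.ndarray

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return map_points(self, pts)


def fit_tps(
    source_pts: np.ndarray,
    target_pts: np.ndarray,
    regularization: float = 0.0,
) -> TPSTransform:
    """Fit a thin-plate spline mapping source points onto target points.

    Requires >= 3 non-collinear source points with no duplicates within
    1e-6 px.  With ``regularization`` 0 the transform reproduces every
    target point exactly; the kernel weights always satisfy the side
    conditions (sum to zero and orthogonal to the source x and y
    coordinates), which makes the map affine far from the landmarks.
    """
    src = np.asarray(source_pts, dtype=float)
    tgt = np.asarray(target_pts, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or src.shape != tgt.shape:
        raise ValueError("source and target must be matching (n, 2) arrays")
    n = len(src)
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    if pdist(src).min() < 1e-6:
        raise ValueError("duplicate source points (closer than 1e-6 px)")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise np.linalg.LinAlgError(
            "degenerate landmark configuration: source points are collinear, "
            "the TPS system is singular"
        )
    K = _kernel(cdist(src, src, "sqeuclidean"))
    if regularization:
        K = K + float(regularization) * np.eye(n)
    P = np.column_stack([np.ones(n), src])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise np.linalg.LinAlgError(f"singular TPS system: {exc}") from exc
    return TPSTransform(control_points=src, weights=sol[:n], affine=sol[n:])


def map_points(t: TPSTransform, pts: np.ndarray) -> np.ndarray:
    """Apply the fitted transform to an (m, 2) array of points."""
    p = np.atleast_2d(np.asarray(pts, dtype=float))
    U = _kernel(cdist(p, t.control_points, "sqeuclidean"))
    P = np.column_stack([np.ones(len(p)), p])
    out = P @ t.affine + U @ t.weights
    return out if np.asarray(pts).ndim == 2 else out[0]


def invert_fit(t: TPSTransform) -> TPSTransform:
    """Fit the spline in the opposite direction (targets -> sources).

    The forward transform reproduces its own targets exactly (at zero
    regularization), so the landmark pairs are recovered by mapping the
    control points; the returned spline interpolates those pairs swapped.
    """
    targets = map_points(t, t.control_points)
    return fit_tps(targets, t.control_points)


def warp_image(
    t: TPSTransform,
    source_img: np.ndarray,
    target_shape: tuple[int, int] | None = None,
    interp: str = "linear",
) -> np.ndarray:
    """Backward-warp a source image into the target frame.

    ``t`` is the forward (source -> target) transform; the warp fits the
    inverse-direction spline through the same landmark pairs and, for each
    target pixel, samples the source image at the mapped location.
    Out-of-bounds samples are filled with 0.
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(
            f"unknown interpolation {interp!r}; choose from {sorted(_INTERP_ORDER)}"
        )
    img = np.asarray(source_img, dtype=float)
    if img.ndim != 2:
        raise ValueError("source image must be 2-D grayscale")
    shape = tuple(target_shape) if target_shape is not None else img.shape
    inv = invert_fit(t)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = map_points(inv, pts)
    coords = np.vstack([src[:, 1], src[:, 0]])  # (row, col) order
    # snap round-off-level overshoots back onto the image edge so that
    # nominally in-bounds samples do not blend with the constant fill
    for ax, n_ax in enumerate(img.shape):
        c = coords[ax]
        c[(c > n_ax - 1) & (c < n_ax - 1 + 1e-9)] = n_ax - 1
        c[(c < 0) & (c > -1e-9)] = 0.0
    vals = map_coordinates(
        img, coords, order=_INTERP_ORDER[interp], mode="constant", cval=0.0
    )
    return vals.reshape(shape)


def save_transform(t: TPSTransform, path: str | Path) -> None:
    """Serialize a transform to JSON for later reuse with other images."""
    data = {
        "control_points": t.control_points.tolist(),
        "weights": t.weights.tolist(),
        "affine": t.affine.tolist(),
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def load_transform(path: str | Path) -> TPSTransform:
    data = json.loads(Path(path).read_text())
    return TPSTransform(
        control_points=np.asarray(data["control_points"], float),
        weights=np.asarray(data["weights"], float),
        affine=np.asarray(data["affine"], float),
    )
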