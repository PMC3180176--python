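"""Synthetic contoured phantoms with known ground-truth deformations.

A phantom emulates a 2-D brain-slice pair: a target image built from
nested smooth blobs with distinct intensities, boundary contours extracted
analytically from the generating shapes (not by segmentation, so contour
error does not contaminate landmark/warp error), and a source image
produced by a smooth random deformation of known form.  The deformation is
a sum of Gaussian radial bumps — deliberately outside the thin-plate-spline
family being fitted — scaled so its maximum displacement magnitude equals a
requested amplitude.  True point correspondences are exported for held-out
TRE evaluation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString
from skimage.draw import polygon as draw_polygon

from .contours import Curve, CurvePair

__all__ = ["GaussianBumpField", "Phantom", "make_phantom", "discretize_landmarks"]


@dataclass
class GaussianBumpField:
    """Smooth displacement field: a sum of Gaussian radial bumps.

    ``map`` sends target-frame coordinates to source-frame coordinates
    (p + displacement); ``inverse`` solves the reverse by fixed-point
    iteration, which converges for the moderate amplitudes used here.
    """

    centers: np.ndarray  # (k, 2)
    sigmas: np.ndarray  # (k,)
    vectors: np.ndarray  # (k, 2)

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        d = np.zeros_like(p)
        for c, s, v in zip(self.centers, self.sigmas, self.vectors):
            r2 = ((p - c) ** 2).sum(axis=1)
            d += np.exp(-r2 / (2.0 * s * s))[:, None] * v
        return d

    def map(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        return p + self.displacement(p)

    def inverse(self, pts: np.ndarray, n_iter: int = 40) -> np.ndarray:
        x = np.atleast_2d(np.asarray(pts, dtype=float))
        y = x.copy()
        for _ in range(n_iter):
            y = x - self.displacement(y)
        return y

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "sigmas": self.sigmas.tolist(),
            "vectors": self.vectors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianBumpField":
        return cls(
            centers=np.asarray(d["centers"], float),
            sigmas=np.asarray(d["sigmas"], float),
            vectors=np.asarray(d["vectors"], float),
        )


@dataclass
class Phantom:
    """A synthetic registration problem with known ground truth."""

    target_img: np.ndarray
    source_img: np.ndarray
    contours_target: list[Curve]
    contours_source: list[Curve]
    gt_deformation: GaussianBumpField
    eval_pairs: tuple[np.ndarray, np.ndarray]  # (target pts, source pts)
    seed: int

    def curve_pairs(self) -> list[CurvePair]:
        by_id = {c.id: c for c in self.contours_source}
        return [CurvePair(source=by_id[c.id], target=c, id=c.id)
                for c in self.contours_target]

    def save(self, outdir: str | Path) -> None:
        """Write target/source PNGs, contour JSONs, eval CSV and truth JSON."""
        from PIL import Image

        from .contours import write_contours_json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, img in [("target.png", self.target_img),
                          ("source.png", self.source_img)]:
            arr = np.clip(np.round(img), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(outdir / name)
        write_contours_json(self.contours_target, outdir / "contours_target.json")
        write_contours_json(self.contours_source, outdir / "contours_source.json")
        p_t, p_s = self.eval_pairs
        with open(outdir / "eval_pairs.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x_src", "y_src", "x_tgt", "y_tgt"])
            for (xt, yt), (xs, ys) in zip(p_t, p_s):
                w.writerow([repr(float(xs)), repr(float(ys)),
                            repr(float(xt)), repr(float(yt))])
        truth = {"seed": self.seed, "gt_deformation": self.gt_deformation.to_dict()}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _blob_boundary(
    center: np.ndarray, radius: float, harmonics: np.ndarray,
    phases: np.ndarray, n_points: int = 200,
) -> np.ndarray:
    """Closed smooth blob boundary r(theta) = r0 (1 + sum a_k cos(k theta + phi))."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_points + 1)
    r = radius * (
        1.0
        + sum(
            a * np.cos((k + 2) * theta + ph)
            for k, (a, ph) in enumerate(zip(harmonics, phases))
        )
    )
    pts = np.column_stack([center[0] + r * np.cos(theta),
                           center[1] + r * np.sin(theta)])
    pts[-1] = pts[0]  # bit-exact closure
    return pts


def _rasterize(shape: tuple[int, int], boundaries, intensities) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    for pts, val in zip(boundaries, intensities):
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        img[rr, cc] = val
    return img


def _is_simple(pts: np.ndarray) -> bool:
    return LineString(pts[:-1]).is_simple  # drop duplicate closing vertex


def make_phantom(
    shape: tuple[int, int] = (128, 128),
    deformation_amplitude: float = 8.0,
    n_structures: int = 2,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> Phantom:
    """Generate a contoured phantom pair with a known smooth deformation.

    Parameters
    ----------
    shape : target/source image shape (rows, cols), at least 64 x 64.
    deformation_amplitude : maximum displacement magnitude in pixels of the
        ground-truth field (0 gives identical source and target geometry).
    n_structures : number of internal structures inside the outer boundary.
    noise_sd : standard deviation of i.i.d. Gaussian intensity noise added
        independently to both images (intensities are on a 0-255 scale).
    seed : seed of the single random generator driving all draws.
    """
    if deformation_amplitude < 0:
        raise ValueError("deformation amplitude must be >= 0")
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("shape must be at least 64 x 64")
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    center = np.array([w / 2.0, h / 2.0])
    last_err = None
    for _ in range(10):
        # --- target geometry: lobed outer boundary + internal structures
        outer_r = 0.36 * min(h, w)
        blob_centers = [center + rng.uniform(-3, 3, 2)]
        blob_radii = [outer_r]
        boundaries = [
            _blob_boundary(
                blob_centers[0], outer_r,
                rng.uniform(0.02, 0.08, 3), rng.uniform(0, 2 * np.pi, 3),
            )
        ]
        for k in range(n_structures):
            ang = 2 * np.pi * (k + rng.uniform(0.1, 0.4)) / n_structures
            off = 0.45 * outer_r * np.array([np.cos(ang), np.sin(ang)])
            blob_centers.append(center + off)
            blob_radii.append(outer_r * rng.uniform(0.22, 0.32))
            boundaries.append(
                _blob_boundary(
                    blob_centers[-1], blob_radii[-1],
                    rng.uniform(0.03, 0.1, 3), rng.uniform(0, 2 * np.pi, 3),
                    n_points=160,
                )
            )
        intensities = [100.0] + [160.0 + (60.0 * j) % 130 for j in range(1, n_structures + 1)]
        target_clean = _rasterize(shape, boundaries, intensities)

        # --- ground-truth deformation: Gaussian bumps whose centers sit
        # on the tissue boundaries and whose vectors follow the local
        # contour tangent, emulating the boundary-parallel shear of tissue
        # processing and in-plane EPI stretch; this is what redistributes
        # arc length along the contours and misplaces interval-based
        # landmark placements
        nb = int(rng.integers(3, 7))
        ctrs, vecs = [], []
        for _b in range(nb):
            bpts = boundaries[int(rng.integers(0, len(boundaries)))]
            j = int(rng.integers(3, len(bpts) - 4))
            ctrs.append(bpts[j] + rng.normal(0, 3, 2))
            tan = bpts[j + 3] - bpts[j - 3]
            tan = tan / np.linalg.norm(tan)
            vecs.append(tan * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0))
        field = GaussianBumpField(
            centers=np.array(ctrs),
            sigmas=rng.uniform(10.0, 30.0, nb),
            vectors=np.array(vecs),
        )
        if deformation_amplitude > 0:
            gy, gx = np.mgrid[0:h:4, 0:w:4]
            grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
            peak = np.linalg.norm(field.displacement(grid), axis=1).max()
            field.vectors *= deformation_amplitude / peak
        else:
            field.vectors[:] = 0.0

        # --- contours: analytic boundaries, split into 4 homologous
        # curves each at shared vertex indices so that sub-curve vertices
        # keep their exact ground-truth correspondence
        contours_target: list[Curve] = []
        contours_source: list[Curve] = []
        ok = True
        for j, pts in enumerate(boundaries):
            src_pts = field.map(pts)
            if not (_is_simple(pts) and _is_simple(src_pts)):
                ok = False
                break
            idx = np.linspace(0, len(pts) - 1, 5).astype(int)
            for k in range(4):
                sl = slice(idx[k], idx[k + 1] + 1)
                contours_target.append(Curve(pts[sl], id=f"c{j}.{k}"))
                contours_source.append(Curve(src_pts[sl], id=f"c{j}.{k}"))
        if not ok:
            last_err = "deformed contour self-intersects"
            continue

        # --- source image: backward resampling through the inverse map --
        yy, xx = np.mgrid[0:h, 0:w]
        pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        back = field.inverse(pix)
        source_clean = map_coordinates(
            target_clean, np.vstack([back[:, 1], back[:, 0]]),
            order=1, mode="constant", cval=0.0,
        ).reshape(shape)

        target_img = target_clean + rng.normal(0.0, noise_sd, shape) if noise_sd else target_clean
        source_img = source_clean + rng.normal(0.0, noise_sd, shape) if noise_sd else source_clean

        # --- held-out true correspondences: anatomical-feature points
        # just inside the structure boundaries, plus interior points
        ev = []
        for _e in range(12):
            b = int(rng.integers(0, len(boundaries)))
            v = boundaries[b][int(rng.integers(0, len(boundaries[b]) - 1))]
            bc = blob_centers[b]
            ev.append(bc + (v - bc) * (1.0 - 2.0 / max(np.linalg.norm(v - bc), 2.0)))
        while len(ev) < 18:
            p = center + rng.uniform(-0.7, 0.7, 2) * outer_r
            if np.linalg.norm(p - center) < 0.68 * outer_r:
                ev.append(p)
        p_t = np.array(ev)
        p_s = field.map(p_t)
        return Phantom(
            target_img=target_img,
            source_img=source_img,
            contours_target=contours_target,
            contours_source=contours_source,
            gt_deformation=field,
            eval_pairs=(p_t, p_s),
            seed=seed,
        )
    raise RuntimeError(
        f"could not generate a valid phantom in 10 attempts: {last_err}"
    )


def discretize_landmarks(
    phantom: Phantom, jitter_px: float, seed: int, n_points: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Sample true correspondences perturbed by Gaussian picking jitter.

    Emulates manually picked discrete landmarks: ``n_points`` true
    correspondences drawn inside the phantom, with i.i.d. Gaussian jitter
    of standard deviation ``jitter_px`` added independently to both sides.
    Returns ``(source points, target points)``.
    """
    if jitter_px < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = phantom.target_img.shape
    center = np.array([w / 2.0, h / 2.0])
    radii = rng.uniform(0.1, 0.65, n_points) * 0.36 * min(h, w)
    angles = rng.uniform(0.0, 2.0 * np.pi, n_points)
    p_t = center + radii[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    p_s = phantom.gt_deformation.map(p_t)
    p_t = p_t + rng.normal(0.0, jitter_px, p_t.shape)
    p_s = p_s + rng.normal(0.0, jitter_px, p_s.shape)
    return p_s, p_t
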