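"""Registration-quality metrics: normalized mutual information and TRE.

NMI = (H(A) + H(B)) / H(A, B) with Shannon entropies in bits over a joint
histogram; ranges from 1 (independent images) to 2 (identical images).
TRE (target registration error) is the array of residual vectors between
warped source evaluation points and their true target positions, reported
as the mean Euclidean magnitude in pixels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .tps import TPSTransform, map_points

__all__ = ["EvalReport", "nmi", "tre"]


@dataclass
class EvalReport:
    """Before/after registration scores for one image pair."""

    nmi_before: float
    nmi_after: float
    tre_before: float | None
    tre_after: float | None
    n_eval_points: int
    bins: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        return cls(**json.loads(Path(path).read_text()))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(
    img_a: np.ndarray,
    img_b: np.ndarray,
    bins: int = 32,
    mask: np.ndarray | None = None,
) -> float:
    """Normalized mutual information of two equally shaped grayscale images.

    The joint histogram uses ``bins`` x ``bins`` equal-width bins spanning
    each image's own min-max range (within ``mask`` when given).  Constant
    images have zero entropy, for which NMI is undefined.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("mask shape must match the images")
        a, b = a[m], b[m]
    av, bv = a.ravel(), b.ravel()
    if av.min() == av.max() or bv.min() == bv.max():
        raise ValueError("entropy zero: constant image, NMI undefined")
    joint, _, _ = np.histogram2d(
        av, bv, bins=bins, range=[[av.min(), av.max()], [bv.min(), bv.max()]]
    )
    p = joint / joint.sum()
    h_a = _entropy(p.sum(axis=1))
    h_b = _entropy(p.sum(axis=0))
    h_ab = _entropy(p.ravel())
    return (h_a + h_b) / h_ab


def tre(
    t: TPSTransform | None,
    p_source: np.ndarray,
    p_target: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Target registration error of a transform on evaluation point pairs.

    Returns ``(mean magnitude, (n, 2) residual vectors)`` where each
    residual is T(p_source) - p_target.  ``t=None`` means the identity
    (the pre-registration error).
    """
    ps = np.atleast_2d(np.asarray(p_source, dtype=float))
    pt = np.atleast_2d(np.asarray(p_target, dtype=float))
    if ps.shape != pt.shape or ps.shape[0] < 1:
        raise ValueError("evaluation point sets must be matching (n, 2) arrays")
    mapped = ps if t is None else map_points(t, ps)
    vectors = mapped - pt
    return float(np.linalg.norm(vectors, axis=1).mean()), vectors
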