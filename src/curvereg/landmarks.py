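"""Landmark generation and optimization on homologous contour curves.

Landmarks are placed iteratively: the first two are fixed at the curve
endpoints; each subsequent landmark is placed at the arc-length midpoint of
the longest source segment, with its homologue at the same fractional
position of the corresponding target segment.  After each placement the new
landmark pair is relaxed — slid along its segments — by minimizing

    M = |k_S / max(k_S) - k_T / max(k_T)| + lam * (d_S / l_S + d_T / l_T)

where k are local curvatures normalized by the maximum curvature of the
sliding segment, d are the arc-length displacements from the placement-time
initial positions, and l are the lengths of the segments the landmark was
inserted into.  The 2-D minimization (source position, target position)
uses the Nelder-Mead simplex with positions kept between the neighboring
landmarks by a large out-of-bounds penalty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .contours import (
    DEFAULT_WINDOW,
    CurvePair,
    arclength_point,
    curvature,
    max_curvature,
)

__all__ = [
    "LandmarkChain",
    "OptimizerParams",
    "init_chain",
    "add_landmark",
    "cost",
    "relax",
    "generate",
    "collect",
    "write_landmarks_csv",
    "read_landmarks_csv",
]

#: Cost assigned to out-of-segment proposals during relaxation.
PENALTY = 1.0e6


@dataclass
class OptimizerParams:
    """Parameters governing landmark generation and relaxation.

    lam : displacement weight (> 0); larger values restrict sliding.
        Default 0.25, the midpoint of the 0.2-0.3 range that works well for
        rodent-brain contours.
    tol_px : convergence threshold on landmark displacement between simplex
        iterations, in pixels.
    max_iter : Nelder-Mead iteration cap per landmark.
    n_landmarks : landmarks per curve (>= 2, including the two endpoints).
    reoptimize_all : if True, after each insertion every interior landmark
        is re-relaxed in sweeps until none moves more than tol_px
        (at most 5 sweeps); if False only the newest pair relaxes.
    """

    lam: float = 0.25
    tol_px: float = 1e-4
    max_iter: int = 500
    n_landmarks: int = 10
    reoptimize_all: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.tol_px <= 0:
            raise ValueError("tol_px must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_landmarks < 2:
            raise ValueError("n_landmarks must be >= 2")


@dataclass
class LandmarkChain:
    """Ordered paired landmarks on one curve pair, as arc-length fractions.

    ``s_source``/``s_target`` are the current positions, strictly increasing
    with fixed 0 and 1 endpoints.  ``s_source_init``/``s_target_init`` hold
    the placement-time positions from which displacements are measured, and
    ``seg_source``/``seg_target`` the (lo, hi) fraction bounds of the
    segment each landmark was inserted into (NaN for the endpoints), frozen
    at insertion for displacement normalization.
    """

    pair: CurvePair
    s_source: np.ndarray
    s_target: np.ndarray
    s_source_init: np.ndarray
    s_target_init: np.ndarray
    seg_source: np.ndarray = field(default=None)  # (n, 2) lo/hi fractions
    seg_target: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        for name in ("s_source", "s_target", "s_source_init", "s_target_init"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.seg_source is None:
            self.seg_source = np.full((self.n_placed, 2), np.nan)
        if self.seg_target is None:
            self.seg_target = np.full((self.n_placed, 2), np.nan)
        self._validate()

    def _validate(self) -> None:
        n = len(self.s_source)
        if n < 2 or len(self.s_target) != n:
            raise ValueError("source and target must hold the same n >= 2 landmarks")
        for s in (self.s_source, self.s_target):
            if s[0] != 0.0 or s[-1] != 1.0:
                raise ValueError("endpoint landmarks must sit at fractions 0 and 1")
            if np.any(np.diff(s) <= 0):
                raise ValueError("landmark fractions must be strictly increasing")

    @property
    def n_placed(self) -> int:
        return len(self.s_source)

    def source_points(self) -> np.ndarray:
        return np.array([arclength_point(self.pair.source, s) for s in self.s_source])

    def target_points(self) -> np.ndarray:
        return np.array([arclength_point(self.pair.target, s) for s in self.s_target])


def init_chain(pair: CurvePair) -> LandmarkChain:
    """Chain with only the two endpoint landmarks, fixed at fractions 0 and 1."""
    ends = np.array([0.0, 1.0])
    return LandmarkChain(
        pair=pair,
        s_source=ends.copy(),
        s_target=ends.copy(),
        s_source_init=ends.copy(),
        s_target_init=ends.copy(),
    )


def add_landmark(chain: LandmarkChain) -> LandmarkChain:
    """Insert a landmark at the arc-length midpoint of the longest source segment.

    The homologue goes at the same fractional position (the midpoint) of the
    corresponding target segment.  Ties in segment length break toward the
    lower-s segment.  Both positions are recorded as the initial positions
    and the enclosing segments are frozen for displacement normalization.
    """
    gaps = np.diff(chain.s_source)  # fractions are arc-length fractions
    k = int(np.argmax(gaps))  # argmax takes the first maximum: low-s tie-break
    s_lo, s_hi = chain.s_source[k], chain.s_source[k + 1]
    t_lo, t_hi = chain.s_target[k], chain.s_target[k + 1]
    s_new = 0.5 * (s_lo + s_hi)
    t_new = 0.5 * (t_lo + t_hi)
    j = k + 1
    return replace(
        chain,
        s_source=np.insert(chain.s_source, j, s_new),
        s_target=np.insert(chain.s_target, j, t_new),
        s_source_init=np.insert(chain.s_source_init, j, s_new),
        s_target_init=np.insert(chain.s_target_init, j, t_new),
        seg_source=np.insert(chain.seg_source, j, [s_lo, s_hi], axis=0),
        seg_target=np.insert(chain.seg_target, j, [t_lo, t_hi], axis=0),
    )


def _cost_at(
    chain: LandmarkChain, i: int, s_src: float, s_tgt: float, lam: float
) -> float:
    """Cost of landmark ``i`` evaluated at candidate fractions (s_src, s_tgt)."""
    src, tgt = chain.pair.source, chain.pair.target
    k_s = curvature(src, s_src)
    k_t = curvature(tgt, s_tgt)
    # curvature normalized over the current sliding span (between neighbors)
    m_s = max_curvature(src, chain.s_source[i - 1], chain.s_source[i + 1])
    m_t = max_curvature(tgt, chain.s_target[i - 1], chain.s_target[i + 1])
    term1 = abs(k_s / m_s - k_t / m_t)
    # displacement normalized by the frozen insertion segment lengths
    l_s = (chain.seg_source[i, 1] - chain.seg_source[i, 0]) * src.length
    l_t = (chain.seg_target[i, 1] - chain.seg_target[i, 0]) * tgt.length
    d_s = abs(s_src - chain.s_source_init[i]) * src.length
    d_t = abs(s_tgt - chain.s_target_init[i]) * tgt.length
    return term1 + lam * (d_s / l_s + d_t / l_t)


def cost(chain: LandmarkChain, i: int, lam: float) -> float:
    """Cost M of interior landmark ``i`` at its current position.

    ``i`` indexes positions along the chain; endpoints (0 and n-1) carry no
    cost and are rejected.
    """
    if not 0 < i < chain.n_placed - 1:
        raise IndexError(f"landmark index {i} is not an interior landmark")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return _cost_at(chain, i, chain.s_source[i], chain.s_target[i], lam)


def relax(chain: LandmarkChain, i: int, params: OptimizerParams) -> LandmarkChain:
    """Slide landmark pair ``i`` along its segments to minimize the cost.

    The cost is minimized over the 2-D variable (source position, target
    position), in arc-length pixels, with the Nelder-Mead simplex using the
    stated stopping rules: simplex displacement below ``tol_px`` or
    ``max_iter`` iterations.  Because the curvature-similarity surface can
    hold several basins along a segment, the simplex is started from the
    current position and additionally refined from the best points of a
    deterministic coarse scan of the sliding rectangle; the best Nelder-Mead
    result is kept.  Proposals outside the open interval between the
    neighboring landmarks — less a minimum-separation margin of up to
    1 px — receive a large penalty, which keeps landmarks on their segments
    and strictly ordered.  The returned cost never exceeds the starting
    cost (the start point is a simplex vertex).
    """
    if not 0 < i < chain.n_placed - 1:
        raise IndexError(f"landmark index {i} is not an interior landmark")
    src, tgt = chain.pair.source, chain.pair.target
    L_s, L_t = src.length, tgt.length
    lo_u, hi_u = chain.s_source[i - 1] * L_s, chain.s_source[i + 1] * L_s
    lo_v, hi_v = chain.s_target[i - 1] * L_t, chain.s_target[i + 1] * L_t
    # keep a minimum separation from the neighbors: sub-pixel-adjacent
    # landmarks carry no information on a pixel grid and make the TPS
    # system nearly singular
    m_u = min(1.0, 0.1 * (hi_u - lo_u))
    m_v = min(1.0, 0.1 * (hi_v - lo_v))

    def objective(x: np.ndarray) -> float:
        u, v = x
        if not (lo_u + m_u < u < hi_u - m_u and lo_v + m_v < v < hi_v - m_v):
            return PENALTY
        return _cost_at(chain, i, u / L_s, v / L_t, params.lam)

    x0 = np.array([chain.s_source[i] * L_s, chain.s_target[i] * L_t])
    # dense scan (~1 px spacing) to locate candidate basins: the
    # curvature-similarity term vanishes along narrow valleys in (s, t)
    # that a coarse scan can step over entirely.  The scan is a vectorized
    # outer sum over the cached per-vertex curvature tables, so it is cheap.
    n_u = int(np.clip(np.ceil(hi_u - lo_u), 9, 121))
    n_v = int(np.clip(np.ceil(hi_v - lo_v), 9, 121))
    us = lo_u + m_u + np.linspace(0.0, 1.0, n_u) * (hi_u - lo_u - 2 * m_u)
    vs = lo_v + m_v + np.linspace(0.0, 1.0, n_v) * (hi_v - lo_v - 2 * m_v)
    ts, ks = src._curvature_samples(DEFAULT_WINDOW)
    tt, kt = tgt._curvature_samples(DEFAULT_WINDOW)
    mx_s = max_curvature(src, chain.s_source[i - 1], chain.s_source[i + 1])
    mx_t = max_curvature(tgt, chain.s_target[i - 1], chain.s_target[i + 1])
    kn_s = np.interp(us, ts, ks) / mx_s
    kn_t = np.interp(vs, tt, kt) / mx_t
    l_s = (chain.seg_source[i, 1] - chain.seg_source[i, 0]) * L_s
    l_t = (chain.seg_target[i, 1] - chain.seg_target[i, 0]) * L_t
    disp_u = params.lam * np.abs(us - chain.s_source_init[i] * L_s) / l_s
    disp_v = params.lam * np.abs(vs - chain.s_target_init[i] * L_t) / l_t
    M = np.abs(kn_s[:, None] - kn_t[None, :]) + disp_u[:, None] + disp_v[None, :]
    flat = np.argsort(M, axis=None, kind="stable")[:3]
    cand = [np.array([us[j // n_v], vs[j % n_v]]) for j in flat]
    starts = [x0] + cand

    best_x, best_f = x0, objective(x0)
    for c in cand:
        fc = objective(c)
        if fc < best_f:
            best_x, best_f = c, fc
    for x_start in starts:
        simplex = [x_start.copy()]
        for d, (lo, hi) in enumerate([(lo_u, hi_u), (lo_v, hi_v)]):
            step = 0.1 * (hi - lo)
            vtx = x_start.copy()
            vtx[d] += step if hi - x_start[d] > x_start[d] - lo else -step
            simplex.append(vtx)
        res = minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            options={
                "initial_simplex": np.array(simplex),
                "xatol": params.tol_px,
                "fatol": 1e-12,
                "maxiter": params.max_iter,
            },
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    u, v = best_x
    if not (lo_u < u < hi_u and lo_v < v < hi_v):  # pragma: no cover
        return chain
    out = replace(
        chain,
        s_source=chain.s_source.copy(),
        s_target=chain.s_target.copy(),
    )
    out.s_source[i] = u / L_s
    out.s_target[i] = v / L_t
    return out


def generate(
    pair: CurvePair, params: OptimizerParams
) -> tuple[LandmarkChain, LandmarkChain]:
    """Generate ``params.n_landmarks`` landmark pairs on a curve pair.

    Returns ``(optimized, nonoptimized)``: the optimized chain relaxes each
    newly inserted landmark (and, with ``reoptimize_all``, sweeps over all
    interior landmarks after every insertion); the nonoptimized chain runs
    the same placement rule with every landmark kept at its initial
    position, for accuracy comparisons.
    """
    opt = init_chain(pair)
    for _ in range(2, params.n_landmarks):
        newest = int(np.argmax(np.diff(opt.s_source))) + 1  # insertion slot
        opt = add_landmark(opt)
        opt = relax(opt, newest, params)
        if params.reoptimize_all:
            for _ in range(5):
                moved = 0.0
                for j in range(1, opt.n_placed - 1):
                    before = np.array([opt.s_source[j], opt.s_target[j]])
                    opt = relax(opt, j, params)
                    after = np.array([opt.s_source[j], opt.s_target[j]])
                    moved = max(
                        moved,
                        abs(after[0] - before[0]) * pair.source.length,
                        abs(after[1] - before[1]) * pair.target.length,
                    )
                if moved <= params.tol_px:
                    break
    non = init_chain(pair)
    for _ in range(2, params.n_landmarks):
        non = add_landmark(non)
    return opt, non


def collect(chains: Sequence[LandmarkChain]) -> tuple[np.ndarray, np.ndarray]:
    """Assemble matched source/target point sets from one or more chains.

    Landmarks are ordered by (pair id, arc-length fraction); duplicate
    source points shared between adjacent curves (their common endpoints)
    are kept once, within a 1e-6 px tolerance.
    """
    if not chains:
        raise ValueError("need at least one chain")
    rows = []
    for ch in sorted(chains, key=lambda c: c.pair.id):
        sp, tp = ch.source_points(), ch.target_points()
        for j in range(ch.n_placed):
            rows.append((ch.pair.id, ch.s_source[j], sp[j], tp[j]))
    src_out: list[np.ndarray] = []
    tgt_out: list[np.ndarray] = []
    for _, _, sp, tp in rows:
        dup = any(np.linalg.norm(sp - q) <= 1e-6 for q in src_out)
        if not dup:
            src_out.append(sp)
            tgt_out.append(tp)
    if len(src_out) != len(tgt_out):  # pragma: no cover - invariant breach
        raise RuntimeError("mismatched landmark counts after deduplication")
    return np.array(src_out), np.array(tgt_out)


def write_landmarks_csv(
    chains: Sequence[LandmarkChain], path: str | Path, optimized: bool
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["pair_id", "index", "x_src", "y_src", "x_tgt", "y_tgt",
             "s_src", "s_tgt", "optimized"]
        )
        for ch in sorted(chains, key=lambda c: c.pair.id):
            sp, tp = ch.source_points(), ch.target_points()
            for j in range(ch.n_placed):
                w.writerow(
                    [ch.pair.id, j,
                     repr(float(sp[j, 0])), repr(float(sp[j, 1])),
                     repr(float(tp[j, 0])), repr(float(tp[j, 1])),
                     repr(float(ch.s_source[j])), repr(float(ch.s_target[j])),
                     optimized]
                )


def read_landmarks_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read matched point pairs from a landmark (or evaluation-point) CSV."""
    src, tgt = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            src.append([float(row["x_src"]), float(row["y_src"])])
            tgt.append([float(row["x_tgt"]), float(row["y_tgt"])])
    return np.asarray(src, float), np.asarray(tgt, float)
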