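import numpy as np
import pytest

from curvereg import Curve, CurvePair


def circle_curve(radius: float, n_points: int = 200, closed: bool = True,
                 center=(0.0, 0.0), span: float = 2.0 * np.pi) -> Curve:
    """Circle (or arc) sampled uniformly in angle."""
    theta = np.linspace(0.0, span, n_points)
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Curve(pts, id=f"circle-r{radius}")


def line_curve(length: float = 100.0, n_points: int = 50) -> Curve:
    x = np.linspace(0.0, length, n_points)
    return Curve(np.column_stack([x, np.zeros_like(x)]), id="line")


def sine_curve(amp: float = 5.0, wavelength: float = 62.8, length: float = 100.0,
               n_points: int = 200, mirror: bool = False) -> Curve:
    x = np.linspace(0.0, length, n_points)
    y = (-amp if mirror else amp) * np.sin(2.0 * np.pi * x / wavelength)
    return Curve(np.column_stack([x, y]), id="sine")


def bumpy_pair(seed: int, length: float = 100.0, n_points: int = 240) -> CurvePair:
    """A homologous pair: baseline curve with one Gaussian bump, the bump
    shifted along the curve on the target — a single clear curvature
    feature at different arc positions."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, length, n_points)
    c_src = rng.uniform(0.3, 0.5) * length
    shift = rng.uniform(0.05, 0.15) * length
    w = rng.uniform(6.0, 12.0)
    a = rng.uniform(4.0, 9.0)
    y_src = a * np.exp(-((x - c_src) ** 2) / (2 * w * w))
    y_tgt = a * np.exp(-((x - c_src - shift) ** 2) / (2 * w * w))
    return CurvePair(
        source=Curve(np.column_stack([x, y_src]), id=f"bump{seed}"),
        target=Curve(np.column_stack([x, y_tgt]), id=f"bump{seed}"),
        id=f"bump{seed}",
    )


@pytest.fixture(scope="session")
def phantom():
    from curvereg import make_phantom

    return make_phantom(seed=1)
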