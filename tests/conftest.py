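import numpy as np
import pytest

from cortopulse.hexgrid import build_hex_grid
from cortopulse.synthetic import PulseSimParams
from cortopulse.traction import GelParams, TractionField
from cortopulse.types import RegionMask


@pytest.fixture
def fast_pulse_params() -> PulseSimParams:
    """Default study conditions at a coarsened raster (0.25 µm pixels).

    All rates, geometry, pulse shape and noise are the generator defaults;
    only the pixel size is coarsened so a full 30 min movie fits in a few
    hundred milliseconds of compute.
    """
    return PulseSimParams(pixel_size_um=0.25)


@pytest.fixture
def toy_grid():
    """Small hexagonal grid (~10 hexagons) for exhaustive-oracle tests."""
    mask = np.ones((18, 25), dtype=bool)
    roi = RegionMask(mask, pixel_size_um=0.5)  # 12.5 x 9 um
    grid = build_hex_grid(roi, hex_radius_um=2.5)
    assert grid.n_hex <= 10
    assert any(len(nb) == 6 for nb in grid.adjacency)
    return grid


def dipole_traction_scene(
    n: int = 64,
    spacing_um: float = 0.8,
    seed: int = 0,
    n_pairs: int = 2,
    sep_um: float = 6.0,
    sigma_um: float = 3.0,
    amp_pa: float = 800.0,
    gel: GelParams | None = None,
) -> TractionField:
    """Balanced contractile force-dipole scene (cell-like, band-limited).

    Each pair is two Gaussian traction patches pulling toward each other, so
    the net force vanishes and the surface displacement decays as 1/r^2,
    i.e. within the field of view.
    """
    gel = gel or GelParams()
    rng = np.random.default_rng(seed)
    x = np.arange(n) * spacing_um
    X, Y = np.meshgrid(x, x)
    L = n * spacing_um
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    for _ in range(n_pairs):
        cx, cy = rng.uniform(0.35 * L, 0.65 * L, 2)
        th = rng.uniform(0, 2 * np.pi)
        dx, dy = 0.5 * sep_um * np.cos(th), 0.5 * sep_um * np.sin(th)
        a = amp_pa * rng.uniform(0.5, 1.0)
        g1 = np.exp(-((X - cx - dx) ** 2 + (Y - cy - dy) ** 2) / (2 * sigma_um**2))
        g2 = np.exp(-((X - cx + dx) ** 2 + (Y - cy + dy) ** 2) / (2 * sigma_um**2))
        tx += -a * np.cos(th) * g1 + a * np.cos(th) * g2
        ty += -a * np.sin(th) * g1 + a * np.sin(th) * g2
    return TractionField((0.0, 0.0), spacing_um, tx, ty, gel=gel)
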