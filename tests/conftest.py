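import numpy as np
import pytest

from g4quant.foci import estimate_foci_threshold, subtract_background
from g4quant.simulate import SimulationConfig, simulate_cell_stack


def flood_fill_count(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Brute-force BFS connected-component labeling (the labeling oracle).

    Independent of scipy/skimage labeling: explicit queue, explicit
    neighbourhood offsets for 6/18/26-connectivity.
    """
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or labels[z, y, x]:
                    continue
                n += 1
                queue = [(z, y, x)]
                labels[z, y, x] = n
                while queue:
                    cz, cy, cx = queue.pop()
                    for dz, dy, dx in offsets:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                            if mask[pz, py, px] and not labels[pz, py, px]:
                                labels[pz, py, px] = n
                                queue.append((pz, py, px))
    return labels, n


def quantify_ready_cell(config: SimulationConfig, experiment_id: str = "exp"):
    """Simulate one cell, subtract its own background, freeze params on it."""
    stack, truth = simulate_cell_stack(config)
    stack = subtract_background(stack, ~truth.cell_mask)
    params = estimate_foci_threshold([stack], experiment_id=experiment_id)
    return stack, truth, params


@pytest.fixture
def separable_cell():
    """A deterministic cell with known planted foci in both compartments."""
    config = SimulationConfig(
        seed=11,
        nuclear_sizes=[3, 5, 8, 12, 20, 30, 45, 60, 80, 100],
        cytoplasmic_sizes=[20, 35, 50, 75, 100],
    )
    return quantify_ready_cell(config)
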