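"""Synthetic inputs with exact ground truth for every pipeline stage.

The generators emulate the four kinds of raw data the analyses consume:

* two-channel z-stacks (DAPI + red foci channel) of single cells, with an
  ellipsoidal nucleus, bright intranuclear nucleoli, and planted punctate
  foci of controlled voxel size in nucleus and cytoplasm over a noisy
  background floor;
* plate-shaped dose-response tables (viability or quenching titrations)
  drawn from a 4PL closed form with multiplicative noise;
* temperature-emission melting tables with a sigmoidal transition;
* dose-pair viability matrices carrying a planted excess over Bliss
  independence.

Every generator is a pure function of its config and seed: identical
arguments give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .dose_response import four_param_logistic
from .imaging import CellROI, ImageStack

__all__ = [
    "SimulationConfig",
    "FocusTruth",
    "ImageGroundTruth",
    "PlacementError",
    "simulate_cell_stack",
    "simulate_plate",
    "simulate_melt",
    "simulate_synergy_matrix",
    "QN302_DOSES_NM",
    "OLAPARIB_DOSES_UM",
]

#: default combination dose grids: QN-302 twofold dilutions 0.04-40 nM,
#: Olaparib twofold dilutions 0.78-50 µM.
QN302_DOSES_NM = tuple(40.0 / 2**k for k in range(10, -1, -1))
OLAPARIB_DOSES_UM = tuple(50.0 / 2**k for k in range(6, -1, -1))


class PlacementError(RuntimeError):
    """Requested foci cannot be placed without violating compartment rules."""


class SimulationConfig(BaseModel):
    """Parameters of a single-cell two-channel stack simulation.

    Geometry follows the imaging protocol: thin stacks of 5 (TASQ) or 7
    (gamma-H2AX) z-slices at 0.3 µm, so objects are strongly anisotropic in
    voxel space. Focus counts are Poisson with per-compartment means, both
    multiplied by ``fold_change`` to emulate treated conditions; explicit
    size lists override the random draws for exact-placement tests.
    """

    shape: tuple[int, int, int] = (5, 96, 96)
    z_spacing_um: float = 0.3
    pixel_size_um: float = 0.108

    nuclear_foci_mean: float = Field(6.0, ge=0)
    cytoplasmic_foci_mean: float = Field(3.0, ge=0)
    fold_change: float = Field(1.0, gt=0)
    nuclear_size_range: tuple[int, int] = (3, 20)
    cytoplasmic_size_range: tuple[int, int] = (20, 60)
    nuclear_sizes: list[int] | None = None
    cytoplasmic_sizes: list[int] | None = None

    n_nucleoli_range: tuple[int, int] = (2, 4)
    nucleolus_size_range: tuple[int, int] = (110, 220)

    background_mean: float = Field(40.0, ge=0)
    background_sd: float = Field(3.0, ge=0)
    cytoplasm_level: float = Field(15.0, ge=0)
    nucleus_level: float = Field(25.0, ge=0)
    focus_amplitude: float = Field(200.0, ge=0)
    nucleolus_amplitude: float = Field(150.0, ge=0)
    dapi_background: float = Field(10.0, ge=0)
    dapi_cytoplasm: float = Field(100.0, ge=0)
    dapi_nucleus: float = Field(1000.0, ge=0)
    dapi_noise_sd: float = Field(20.0, ge=0)
    dapi_gain: float = Field(1.0, gt=0)

    separable: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.shape[0] not in (5, 7):
            raise ValueError("z count must be 5 or 7 for protocol-faithful stacks")
        if self.shape[1] < 48 or self.shape[2] < 48:
            raise ValueError("grid too small to contain a nucleus plus cytoplasmic margin")
        for lo, hi in (
            self.nuclear_size_range,
            self.cytoplasmic_size_range,
            self.nucleolus_size_range,
        ):
            if lo < 1 or hi < lo:
                raise ValueError("size ranges must satisfy 1 <= lo <= hi")
        return self


@dataclass(frozen=True)
class FocusTruth:
    compartment: str  # "nuclear" or "cytoplasmic"
    voxel_count: int
    centroid: tuple[float, float, float]  # (z, y, x)


@dataclass
class ImageGroundTruth:
    """Exact truth for one simulated cell stack."""

    nucleus_mask: np.ndarray
    nucleolus_mask: np.ndarray
    cell_mask: np.ndarray
    foci: list[FocusTruth]
    background_level: float
    seed: int

    def validate(self) -> None:
        """Assert internal consistency (masks nested, compartments honest)."""
        assert not np.any(self.nucleolus_mask & ~self.nucleus_mask), (
            "nucleolus must lie inside the nucleus"
        )
        assert not np.any(self.nucleus_mask & ~self.cell_mask)
        for f in self.foci:
            assert f.voxel_count >= 1
            zyx = tuple(int(round(c)) for c in f.centroid)
            inside = bool(self.nucleus_mask[zyx])
            if f.compartment == "nuclear":
                assert inside, f"nuclear focus centroid {zyx} outside nucleus"
            elif f.compartment == "cytoplasmic":
                assert not inside, f"cytoplasmic focus centroid {zyx} inside nucleus"
            else:
                raise AssertionError(f"unknown compartment {f.compartment!r}")

    def counts(self) -> dict[str, int]:
        out = {"nuclear": 0, "cytoplasmic": 0}
        for f in self.foci:
            out[f.compartment] += 1
        return out

    def roi(self, roi_id: str = "cell-0") -> CellROI:
        return CellROI(roi_id=roi_id, mask=self.cell_mask, provenance="synthetic")

    def write(self, path: str | Path) -> None:
        payload = {
            "background_level": self.background_level,
            "seed": self.seed,
            "foci": [
                {
                    "compartment": f.compartment,
                    "voxel_count": f.voxel_count,
                    "centroid": list(f.centroid),
                }
                for f in self.foci
            ],
            "nucleus_voxels": int(self.nucleus_mask.sum()),
            "nucleolus_voxels": int(self.nucleolus_mask.sum()),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ----------------------------------------------------------------- geometry

def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _dilate26(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, structure=np.ones((3, 3, 3), bool))


def _erode26(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    return binary_erosion(mask, structure=np.ones((3, 3, 3), bool))


def _blob_voxels(shape, center, n, z_weight):
    """The ``n`` grid voxels nearest ``center`` under an anisotropic metric.

    Sorting by (distance, dz, dy, dx) makes the set deterministic; a
    distance-ball is connected under 26-connectivity, and taking exactly the
    first ``n`` voxels realises a blob thresholded at whatever level yields
    the target voxel count.
    """
    # window radius generous enough to contain n voxels of the ellipsoidal ball
    r = int(np.ceil((3.0 * n * z_weight / (4.0 * np.pi)) ** (1.0 / 3.0))) + 3
    rz = max(1, int(np.ceil(r / z_weight)) + 1)
    cz, cy, cx = center
    z0, z1 = max(0, cz - rz), min(shape[0], cz + rz + 1)
    y0, y1 = max(0, cy - r), min(shape[1], cy + r + 1)
    x0, x1 = max(0, cx - r), min(shape[2], cx + r + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    zz, yy, xx = zz.ravel(), yy.ravel(), xx.ravel()
    d = np.sqrt((z_weight * (zz - cz)) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    # ties resolved toward the central z-plane first, then lexicographically
    order = np.lexsort((xx, yy, np.abs(zz - cz), d))
    if len(order) < n:
        return None
    sel = order[:n]
    return zz[sel], yy[sel], xx[sel], d[sel]


def _place_blobs(
    rng, shape, sizes, allowed, blocked, z_weight, separable
):
    """Place blobs of exact voxel counts inside ``allowed``.

    In separable mode a placed blob additionally blocks its 26-neighbourhood
    so no two objects touch (they stay distinct connected components).
    Blobs are placed largest-first (big objects need the scarcest space);
    results are returned in the requested size order.
    Returns (list of (zidx, yidx, xidx, dist), updated blocked mask).
    """
    placed: list = [None] * len(sizes)
    if sizes and not allowed.any():
        raise PlacementError("no admissible voxels for blob placement")
    order = sorted(range(len(sizes)), key=lambda i: -sizes[i])
    for i in order:
        size = sizes[i]
        cand = np.argwhere(allowed & ~blocked if separable else allowed)
        if len(cand) == 0:
            raise PlacementError(f"no admissible voxels left for a {size}-voxel blob")
        # random search first (cheap in the common case), then exhaust the
        # remaining candidate centres so failure means genuinely no room
        tries = rng.permutation(len(cand))
        ok = False
        for t in tries:
            cz, cy, cx = cand[t]
            blob = _blob_voxels(shape, (int(cz), int(cy), int(cx)), size, z_weight)
            if blob is None:
                continue
            zi, yi, xi, d = blob
            if not allowed[zi, yi, xi].all():
                continue
            if separable and blocked[zi, yi, xi].any():
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place a {size}-voxel blob; all {len(tries)} "
                "admissible centres exhausted"
            )
        placed[i] = (zi, yi, xi, d)
        if separable:
            m = np.zeros(shape, bool)
            m[zi, yi, xi] = True
            blocked |= _dilate26(m)
        else:
            blocked[zi, yi, xi] = True
    return placed, blocked


# ---------------------------------------------------------------- simulator

def simulate_cell_stack(config: SimulationConfig) -> tuple[ImageStack, ImageGroundTruth]:
    """Simulate one two-channel cell stack plus its exact ground truth.

    The DAPI channel shows a bright nuclear ellipsoid over dim cytoplasm;
    the foci channel carries camera noise, diffuse cellular staining,
    2-4 bright nucleolar blobs (>100 voxels each) and the planted foci.
    Foci are added on exact voxel sets, so ground-truth voxel counts are
    literal. In separable mode no two objects touch under 26-connectivity.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    z_weight = config.z_spacing_um / config.pixel_size_um

    # cell outline: one 2D ellipse spanning all z (the ROI convention);
    # nucleus: a 3D ellipsoid with mild lateral jitter
    cy = ny / 2 + rng.uniform(-2, 2)
    cx = nx / 2 + rng.uniform(-2, 2)
    cell2d = _ellipsoid((1, ny, nx), (0, cy, cx), (1.0, 0.44 * ny, 0.44 * nx))[0]
    cell_mask = np.broadcast_to(cell2d, (nz, ny, nx)).copy()
    nucleus_mask = _ellipsoid(
        (nz, ny, nx),
        ((nz - 1) / 2, cy, cx),
        (0.52 * nz, 0.30 * ny, 0.30 * nx),
    )
    nucleus_mask &= cell_mask

    # admissible cores keep planted objects clear of compartment borders so
    # segmentation cannot flip their any-overlap classification
    nucleus_core = _erode26(nucleus_mask)
    cytoplasm_core = _erode26(cell_mask) & ~_dilate26(_dilate26(nucleus_mask))

    blocked = np.zeros(config.shape, bool)

    n_nucleoli = int(rng.integers(config.n_nucleoli_range[0], config.n_nucleoli_range[1] + 1))
    nucleolus_sizes = [
        int(rng.integers(config.nucleolus_size_range[0], config.nucleolus_size_range[1] + 1))
        for _ in range(n_nucleoli)
    ]

    if config.nuclear_sizes is not None:
        nuclear_sizes = [int(s) for s in config.nuclear_sizes]
    else:
        n = rng.poisson(config.nuclear_foci_mean * config.fold_change)
        nuclear_sizes = [
            int(rng.integers(config.nuclear_size_range[0], config.nuclear_size_range[1] + 1))
            for _ in range(n)
        ]
    if config.cytoplasmic_sizes is not None:
        cyto_sizes = [int(s) for s in config.cytoplasmic_sizes]
    else:
        n = rng.poisson(config.cytoplasmic_foci_mean * config.fold_change)
        cyto_sizes = [
            int(
                rng.integers(
                    config.cytoplasmic_size_range[0], config.cytoplasmic_size_range[1] + 1
                )
            )
            for _ in range(n)
        ]

    # nucleoli and nuclear foci compete for the same compartment: place them
    # in one pass so the largest objects claim space first
    nuclear_side, blocked = _place_blobs(
        rng, config.shape, nucleolus_sizes + nuclear_sizes, nucleus_core, blocked,
        z_weight, config.separable,
    )
    nucleoli = nuclear_side[: len(nucleolus_sizes)]
    nuclear_blobs = nuclear_side[len(nucleolus_sizes):]
    cyto_blobs, blocked = _place_blobs(
        rng, config.shape, cyto_sizes, cytoplasm_core, blocked,
        z_weight, config.separable,
    )

    # ---- channels
    foci_ch = rng.normal(config.background_mean, config.background_sd, config.shape)
    foci_ch += config.cytoplasm_level * cell_mask
    foci_ch += config.nucleus_level * nucleus_mask

    nucleolus_mask = np.zeros(config.shape, bool)
    for zi, yi, xi, d in nucleoli:
        nucleolus_mask[zi, yi, xi] = True
        dmax = d.max() if d.max() > 0 else 1.0
        foci_ch[zi, yi, xi] += config.nucleolus_amplitude * (0.85 + 0.15 * (1 - d / dmax))

    foci_truth: list[FocusTruth] = []
    for compartment, blobs in (("nuclear", nuclear_blobs), ("cytoplasmic", cyto_blobs)):
        for zi, yi, xi, d in blobs:
            dmax = d.max() if d.max() > 0 else 1.0
            foci_ch[zi, yi, xi] += config.focus_amplitude * (0.6 + 0.4 * (1 - d / dmax))
            foci_truth.append(
                FocusTruth(
                    compartment=compartment,
                    voxel_count=int(len(zi)),
                    centroid=(float(zi.mean()), float(yi.mean()), float(xi.mean())),
                )
            )

    dapi = rng.normal(config.dapi_background, config.dapi_noise_sd, config.shape)
    dapi += config.dapi_cytoplasm * cell_mask
    dapi += (config.dapi_nucleus - config.dapi_cytoplasm) * nucleus_mask
    dapi *= config.dapi_gain

    stack = ImageStack(
        channels={"dapi": np.clip(dapi, 0, None), "foci": np.clip(foci_ch, 0, None)},
        z_spacing_um=config.z_spacing_um,
        pixel_size_um=config.pixel_size_um,
        provenance={"generator": "simulate_cell_stack", "seed": config.seed},
    )
    truth = ImageGroundTruth(
        nucleus_mask=nucleus_mask,
        nucleolus_mask=nucleolus_mask,
        cell_mask=cell_mask,
        foci=foci_truth,
        background_level=config.background_mean,
        seed=config.seed,
    )
    truth.validate()
    return stack, truth


# ------------------------------------------------------------ plate readouts

_CURVE_KINDS = ("srb_viability", "fqa_classical", "fqa_reverse")


def simulate_plate(
    curve_kind: str,
    true_params: dict,
    doses: np.ndarray,
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    n_nt_wells: int = 3,
) -> pd.DataFrame:
    """Simulate a plate-shaped dose-response table from a 4PL closed form.

    ``true_params`` carries ``bottom``, ``top``, ``mid`` and ``hill``;
    responses get multiplicative Gaussian noise of coefficient of variation
    ``noise_cv``. Viability tables come back as (well, condition, dose,
    unit, absorbance) with untreated (NT) wells at dose 0; FQA tables as
    (well, condition, dose, unit, F_T0, F_T60).
    """
    if curve_kind not in _CURVE_KINDS:
        raise ValueError(f"unknown curve kind {curve_kind!r}; expected one of {_CURVE_KINDS}")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (NT wells are added separately)")
    if len(np.unique(doses)) < 5:
        raise ValueError("need >= 5 dose levels")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    p = dict(true_params)
    unit = p.pop("unit", "nM")
    rows = []
    well = 0

    def noisy(value):
        return value * (1.0 + noise_cv * rng.standard_normal()) if noise_cv > 0 else value

    if curve_kind == "srb_viability":
        nt_abs = p.pop("nt_absorbance", 1.0)
        for _ in range(n_nt_wells):
            rows.append(("W%03d" % well, "NT", 0.0, unit, noisy(nt_abs)))
            well += 1
        for _ in range(replicates):
            for d in doses:
                v = four_param_logistic(d, p["bottom"], p["top"], p["mid"], p["hill"])
                rows.append(("W%03d" % well, "treated", float(d), unit, noisy(v / 100.0 * nt_abs)))
                well += 1
        return pd.DataFrame(rows, columns=["well", "condition", "dose", "unit", "absorbance"])

    # FQA: response is the percent of T0 fluorescence remaining at T60
    f0_mean = p.pop("f_t0", 1000.0)
    for _ in range(n_nt_wells):
        f0 = noisy(f0_mean)
        rows.append(("W%03d" % well, "NT", 0.0, unit, f0, noisy(f0)))
        well += 1
    for _ in range(replicates):
        for d in doses:
            frac = four_param_logistic(d, p["bottom"], p["top"], p["mid"], p["hill"]) / 100.0
            f0 = noisy(f0_mean)
            rows.append(("W%03d" % well, "treated", float(d), unit, f0, f0 * noisy(frac)))
            well += 1
    return pd.DataFrame(
        rows, columns=["well", "condition", "dose", "unit", "F_T0", "F_T60"]
    )


def simulate_melt(
    t_half_true: float,
    slope: float = 2.0,
    temperatures: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    gain: float = 1.0,
    offset: float = 0.0,
    series: str = "melt",
) -> pd.DataFrame:
    """Simulate a FRET-melting heating ramp (default 25-90 °C in 1 °C steps).

    Reporter emission rises sigmoidally with temperature, crossing half-range
    at ``t_half_true``; ``slope`` is the logistic width in °C. ``gain`` and
    ``offset`` mimic arbitrary instrument scaling (removed downstream by
    min-max normalisation); ``noise_sd`` is additive, in percent of range.
    """
    if temperatures is None:
        temperatures = np.arange(25.0, 91.0, 1.0)
    temperatures = np.asarray(temperatures, dtype=float)
    if not (temperatures.min() <= t_half_true <= temperatures.max()):
        raise ValueError("t_half_true outside the temperature range")
    rng = np.random.default_rng(seed)
    em = 100.0 / (1.0 + np.exp(-(temperatures - t_half_true) / slope))
    if noise_sd > 0:
        em = em + noise_sd * rng.standard_normal(len(temperatures))
    return pd.DataFrame(
        {
            "temperature_C": temperatures,
            "emission": offset + gain * em,
            "ramp": "heating",
            "series": series,
        }
    )


def simulate_synergy_matrix(
    single_agent_params_a: dict,
    single_agent_params_b: dict,
    planted_excess: float = 0.0,
    doses_a: np.ndarray = QN302_DOSES_NM,
    doses_b: np.ndarray = OLAPARIB_DOSES_UM,
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dose-pair viability matrix in long format.

    Monotherapy inhibitions follow each agent's 4PL; every combination cell
    is the Bliss-independence expectation plus ``planted_excess`` percentage
    points (clipped to [0, 1] as a fraction) before multiplicative noise.
    Zero-dose margins (monotherapies and the untreated corner) are included.
    Columns: dose_a, unit_a, dose_b, unit_b, replicate, viability_pct.
    """
    if not -100.0 <= planted_excess <= 100.0:
        raise ValueError("planted_excess must lie in [-100, 100] percentage points")
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if np.any(doses_a <= 0) or np.any(doses_b <= 0):
        raise ValueError("dose grids must be positive; zero-dose margins are added here")
    rng = np.random.default_rng(seed)
    pa, pb = dict(single_agent_params_a), dict(single_agent_params_b)
    unit_a, unit_b = pa.pop("unit", "nM"), pb.pop("unit", "uM")

    def inhibition(params, dose):
        if dose == 0:
            return 0.0
        v = four_param_logistic(dose, params["bottom"], params["top"], params["mid"], params["hill"])
        return 1.0 - np.clip(v, 0.0, 100.0) / 100.0

    rows = []
    grid_a = np.concatenate([[0.0], doses_a])
    grid_b = np.concatenate([[0.0], doses_b])
    for rep in range(1, replicates + 1):
        for da in grid_a:
            fa = inhibition(pa, da)
            for db in grid_b:
                fb = inhibition(pb, db)
                f = fa + fb - fa * fb
                if da > 0 and db > 0:
                    f = f + planted_excess / 100.0
                f = float(np.clip(f, 0.0, 1.0))
                v = 100.0 * (1.0 - f)
                if noise_cv > 0:
                    v = v * (1.0 + noise_cv * rng.standard_normal())
                rows.append((float(da), unit_a, float(db), unit_b, rep, v))
    return pd.DataFrame(
        rows, columns=["dose_a", "unit_a", "dose_b", "unit_b", "replicate", "viability_pct"]
    )
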