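"""Per-cell 3D foci quantification.

The pipeline mirrors the image-analysis procedure used for TASQ-based G4
chemodetection and gamma-H2AX immunodetection:

1. subtract the background estimated in a cell-free region;
2. clear all channels outside the outlined cell (ROI);
3. segment the nucleus from DAPI (Otsu within the ROI, hole filling,
   largest connected component);
4. segment foci in the red channel with parameters frozen once per
   experiment, label them in 3D (26-connectivity by default);
5. classify components as nuclear / cytoplasmic / nucleolar and apply the
   compartment-specific voxel-size windows: nuclear foci 3-100 voxels,
   cytoplasmic foci 20-100 voxels, nucleoli are nuclear objects >100 voxels
   (counted separately, excluded from nuclear foci);
6. flag outlier cells (aberrant DAPI, missing nucleoli) and summarise per
   condition: per-experiment means first, then across-experiment mean ± SD,
   fold change and NT-corrected delta.

Counts produced this way are convention-dependent (threshold rule,
connectivity); they are meant to reveal trends between conditions, not
absolute numbers of molecular targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imaging import CellROI, ImageStack

__all__ = [
    "FociParams",
    "Focus",
    "CellQuant",
    "ConditionSummary",
    "NUCLEAR_SIZE_WINDOW",
    "CYTOPLASMIC_SIZE_WINDOW",
    "NUCLEOLUS_MIN_VOXELS",
    "subtract_background",
    "clear_outside_roi",
    "segment_nucleus",
    "estimate_foci_threshold",
    "segment_foci",
    "classify_and_filter",
    "quantify_cell",
    "flag_outliers",
    "summarize_condition",
    "cells_to_frame",
]

#: voxel-size windows for retained foci (inclusive bounds)
NUCLEAR_SIZE_WINDOW = (3, 100)
CYTOPLASMIC_SIZE_WINDOW = (20, 100)
#: nuclear objects strictly larger than this are nucleoli
NUCLEOLUS_MIN_VOXELS = 100
#: minimum gamma-H2AX focus size (voxels); not stated by the protocol,
#: chosen to reject single-voxel noise
GH2AX_MIN_VOXELS = 2


class FociQuantError(ValueError):
    pass


class ExperimentMismatchError(RuntimeError):
    """Segmentation params were frozen for a different experiment."""


@dataclass
class FociParams:
    """Foci-segmentation parameters, frozen once per experiment.

    The threshold is absolute intensity (background mean + k·SD estimated
    from the untreated fields of the experiment); ``connectivity`` is the
    3D neighbourhood used for labeling (6, 18 or 26). Reusing one params
    object across experiments is an error unless ``allow_reuse`` is set,
    enforcing the same-parameters-within-one-experiment rule.
    """

    threshold: float
    experiment_id: str
    k: float = 3.0
    connectivity: int = 26
    background_mean: float | None = None
    allow_reuse: bool = False

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise FociQuantError("connectivity must be 6, 18 or 26")
        if self.background_mean is not None and self.threshold < self.background_mean:
            raise FociQuantError("threshold below background mean")

    def check_experiment(self, experiment_id: str) -> None:
        if experiment_id != self.experiment_id and not self.allow_reuse:
            raise ExperimentMismatchError(
                f"params frozen for experiment {self.experiment_id!r} reused for "
                f"{experiment_id!r}; set allow_reuse=True to override"
            )


@dataclass
class Focus:
    """One retained connected component in the foci channel."""

    label: int
    voxel_count: int
    compartment: str  # nuclear | cytoplasmic | nucleolar
    total_intensity: float
    mean_intensity: float
    bbox: tuple[int, int, int, int, int, int]  # (z0, y0, x0, z1, y1, x1), half-open
    centroid: tuple[float, float, float]


@dataclass
class CellQuant:
    """Quantification result for one outlined cell."""

    roi_id: str
    nucleus_mask: np.ndarray
    nucleolus_mask: np.ndarray
    foci: list[Focus]
    discarded: list[dict]
    dapi_volume: int
    dapi_intensity: float
    qc_flags: set[str] = field(default_factory=set)
    excluded: bool = False

    def count(self, compartment: str) -> int:
        return sum(1 for f in self.foci if f.compartment == compartment)

    @property
    def nuclear_count(self) -> int:
        return self.count("nuclear")

    @property
    def cytoplasmic_count(self) -> int:
        return self.count("cytoplasmic")

    @property
    def nucleolar_count(self) -> int:
        return self.count("nucleolar")

    @property
    def whole_cell_count(self) -> int:
        return self.nuclear_count + self.cytoplasmic_count

    def volume(self, compartment: str) -> int:
        return sum(f.voxel_count for f in self.foci if f.compartment == compartment)

    def intensity(self, compartment: str) -> float:
        return sum(f.total_intensity for f in self.foci if f.compartment == compartment)


@dataclass
class ConditionSummary:
    """Across-experiment summary of a per-cell foci metric for one condition."""

    condition: str
    metric: str
    per_experiment_means: dict[str, float]
    mean: float
    sd: float
    fold_change: float | None
    delta: float
    n_cells: int


# ------------------------------------------------------------------- stages

def subtract_background(
    stack: ImageStack, background: float | np.ndarray, channel: str = "foci"
) -> ImageStack:
    """Subtract the background level from the foci channel, floored at zero.

    ``background`` is either a constant or a boolean mask over a cell-free
    region, in which case the estimate is the mean intensity of that region.
    The estimate is recorded in the stack provenance.
    """
    if isinstance(background, np.ndarray):
        mask = np.asarray(background, dtype=bool)
        if not mask.any():
            raise FociQuantError("background region is empty")
        estimate = float(stack.channels[channel][mask].mean())
    else:
        estimate = float(background)
        if estimate < 0:
            raise FociQuantError("background constant must be non-negative")
    out = stack.copy()
    out.channels[channel] = np.clip(out.channels[channel] - estimate, 0.0, None)
    out.provenance["background_estimate"] = estimate
    return out


def clear_outside_roi(stack: ImageStack, roi: CellROI) -> ImageStack:
    """Zero every channel outside the outlined cell."""
    if roi.mask.shape != stack.shape:
        raise FociQuantError(
            f"ROI shape {roi.mask.shape} does not match stack shape {stack.shape}"
        )
    if not roi.mask.any():
        raise FociQuantError(f"ROI {roi.roi_id!r} is empty after clipping to the stack")
    out = stack.copy()
    for name in out.channels:
        out.channels[name] = np.where(roi.mask, out.channels[name], 0.0)
    out.provenance["roi_id"] = roi.roi_id
    return out


def segment_nucleus(stack: ImageStack, roi: CellROI | None = None) -> np.ndarray:
    """Segment the nucleus from the DAPI channel.

    Otsu threshold restricted to the ROI, 3D hole filling, then the largest
    connected component only (one nucleus per outlined cell).
    """
    dapi = stack.channels["dapi"]
    region = roi.mask if roi is not None else np.ones(dapi.shape, bool)
    values = dapi[region]
    if values.size == 0:
        raise FociQuantError("ROI does not intersect the stack")
    if np.allclose(values, values.flat[0]):
        raise FociQuantError("DAPI is constant within the ROI; cannot segment a nucleus")
    thr = threshold_otsu(values)
    mask = (dapi > thr) & region
    if not mask.any():
        raise FociQuantError("no DAPI voxels above the Otsu threshold")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def estimate_foci_threshold(
    nt_stacks: list[ImageStack],
    experiment_id: str,
    k: float = 3.0,
    connectivity: int = 26,
    channel: str = "foci",
) -> FociParams:
    """Freeze foci-segmentation parameters from an experiment's NT fields.

    Threshold = mean + k·SD of the foci-channel intensities over all
    untreated fields (after the same background subtraction the pipeline
    applies), used unchanged for every condition of that experiment.
    """
    if not nt_stacks:
        raise FociQuantError("need at least one untreated field to estimate the threshold")
    values = np.concatenate([s.channels[channel].ravel() for s in nt_stacks])
    mean, sd = float(values.mean()), float(values.std())
    return FociParams(
        threshold=mean + k * sd,
        experiment_id=experiment_id,
        k=k,
        connectivity=connectivity,
        background_mean=mean,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """3D connected-component labeling of a binary mask."""
    if connectivity not in _STRUCTURES:
        raise FociQuantError("connectivity must be 6, 18 or 26")
    labels, n = ndimage.label(np.asarray(mask, bool), structure=_STRUCTURES[connectivity])
    return labels, int(n)


def segment_foci(
    stack: ImageStack,
    params: FociParams,
    experiment_id: str | None = None,
    channel: str = "foci",
) -> tuple[np.ndarray, int]:
    """Threshold the foci channel and label connected components in 3D.

    ``experiment_id`` (when given) is checked against the experiment the
    params were frozen for; a mismatch raises unless the params explicitly
    allow reuse.
    """
    if experiment_id is not None:
        params.check_experiment(experiment_id)
    mask = stack.channels[channel] > params.threshold
    return label_components(mask, params.connectivity)


def _component_focus(labels, image, lab, compartment) -> Focus:
    idx = labels == lab
    zs, ys, xs = np.nonzero(idx)
    vals = image[idx]
    return Focus(
        label=int(lab),
        voxel_count=int(idx.sum()),
        compartment=compartment,
        total_intensity=float(vals.sum()),
        mean_intensity=float(vals.mean()),
        bbox=(
            int(zs.min()), int(ys.min()), int(xs.min()),
            int(zs.max()) + 1, int(ys.max()) + 1, int(xs.max()) + 1,
        ),
        centroid=(float(zs.mean()), float(ys.mean()), float(xs.mean())),
    )


def classify_and_filter(
    labels: np.ndarray,
    n_labels: int,
    nucleus_mask: np.ndarray,
    mode: str = "tasq",
    intensity: np.ndarray | None = None,
    gh2ax_min_voxels: int = GH2AX_MIN_VOXELS,
) -> tuple[list[Focus], list[dict]]:
    """Assign components to compartments and apply the voxel-size windows.

    TASQ mode: a component sharing any voxel with the nucleus mask is on
    the nuclear side; nuclear components >100 voxels are nucleoli (kept in
    the nucleolar list, excluded from nuclear foci); nuclear foci must span
    3-100 voxels and cytoplasmic foci 20-100 voxels. Oversized cytoplasmic
    components are discarded (no cytoplasmic analogue of a nucleolus).

    gamma-H2AX mode: only nucleus-overlapping components are retained,
    at ``gh2ax_min_voxels`` or larger.

    Returns the retained foci and a log of discarded components with the
    reason for each; every component lands in exactly one of the two lists.
    """
    if labels.shape != nucleus_mask.shape:
        raise FociQuantError("labels and nucleus mask must share one shape")
    if mode not in ("tasq", "gh2ax"):
        raise FociQuantError(f"unknown mode {mode!r}")
    if intensity is None:
        intensity = np.zeros(labels.shape)

    kept: list[Focus] = []
    discarded: list[dict] = []
    # voxel counts and nucleus overlap per label, in one pass each
    idx = np.arange(1, n_labels + 1)
    if n_labels == 0:
        return kept, discarded
    sizes = ndimage.sum_labels(np.ones(labels.shape), labels, index=idx).astype(int)
    overlap = ndimage.sum_labels(nucleus_mask.astype(float), labels, index=idx) > 0

    for lab, size, nuclear_side in zip(idx, sizes, overlap):
        if mode == "gh2ax":
            if not nuclear_side:
                discarded.append({"label": int(lab), "size": int(size), "reason": "outside nucleus"})
            elif size < gh2ax_min_voxels:
                discarded.append({"label": int(lab), "size": int(size), "reason": "below minimum size"})
            else:
                kept.append(_component_focus(labels, intensity, lab, "nuclear"))
            continue
        if nuclear_side:
            if size > NUCLEOLUS_MIN_VOXELS:
                kept.append(_component_focus(labels, intensity, lab, "nucleolar"))
            elif NUCLEAR_SIZE_WINDOW[0] <= size <= NUCLEAR_SIZE_WINDOW[1]:
                kept.append(_component_focus(labels, intensity, lab, "nuclear"))
            else:
                discarded.append(
                    {"label": int(lab), "size": int(size), "reason": "nuclear below 3 voxels"}
                )
        else:
            if CYTOPLASMIC_SIZE_WINDOW[0] <= size <= CYTOPLASMIC_SIZE_WINDOW[1]:
                kept.append(_component_focus(labels, intensity, lab, "cytoplasmic"))
            elif size < CYTOPLASMIC_SIZE_WINDOW[0]:
                discarded.append(
                    {"label": int(lab), "size": int(size), "reason": "cytoplasmic below 20 voxels"}
                )
            else:
                discarded.append(
                    {"label": int(lab), "size": int(size), "reason": "cytoplasmic above 100 voxels"}
                )
    return kept, discarded


def quantify_cell(
    stack: ImageStack,
    roi: CellROI,
    params: FociParams,
    mode: str = "tasq",
    experiment_id: str | None = None,
    background: float | np.ndarray | None = None,
) -> CellQuant:
    """Run the full per-cell pipeline and collect counts, volumes, QC metrics.

    ``background`` may be supplied if the stack has not been
    background-subtracted yet; otherwise the stack is used as-is.
    """
    try:
        if background is not None:
            stack = subtract_background(stack, background)
        cleared = clear_outside_roi(stack, roi)
        nucleus = segment_nucleus(cleared, roi)
        labels, n = segment_foci(cleared, params, experiment_id=experiment_id)
        foci, discarded = classify_and_filter(
            labels, n, nucleus, mode=mode, intensity=cleared.channels["foci"]
        )
    except (FociQuantError, ExperimentMismatchError) as exc:
        raise type(exc)(f"[roi {roi.roi_id}] {exc}") from exc

    nucleolus_mask = np.zeros(stack.shape, bool)
    for f in foci:
        if f.compartment == "nucleolar":
            nucleolus_mask |= labels == f.label
    dapi = cleared.channels["dapi"]
    return CellQuant(
        roi_id=roi.roi_id,
        nucleus_mask=nucleus,
        nucleolus_mask=nucleolus_mask,
        foci=foci,
        discarded=discarded,
        dapi_volume=int(nucleus.sum()),
        dapi_intensity=float(dapi[nucleus].sum()),
    )


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values, dtype=float)
    return (values - med) / (1.4826 * mad)


def flag_outliers(
    cells: list[CellQuant], mode: str = "tasq", z_limit: float = 3.0
) -> list[CellQuant]:
    """Flag aberrant cells; they stay in the output, marked ``excluded``.

    A cell is flagged when its DAPI volume or integrated DAPI intensity has
    a robust z-score (median/MAD) beyond ±``z_limit``, or — in TASQ mode —
    when no nucleolus was segmented (a sign the cell was mis-outlined).
    With fewer than 5 cells no flagging is attempted.
    """
    if len(cells) < 5:
        warnings.warn("fewer than 5 cells: outlier flagging skipped", stacklevel=2)
        return cells
    vol_z = _robust_z(np.array([c.dapi_volume for c in cells], dtype=float))
    int_z = _robust_z(np.array([c.dapi_intensity for c in cells], dtype=float))
    for c, zv, zi in zip(cells, vol_z, int_z):
        if abs(zv) > z_limit:
            c.qc_flags.add("aberrant DAPI volume")
        if abs(zi) > z_limit:
            c.qc_flags.add("DAPI missing or lowered" if zi < 0 else "aberrant DAPI intensity")
        if mode == "tasq" and c.nucleolar_count == 0:
            c.qc_flags.add("nucleoli not segmented")
        c.excluded = bool(c.qc_flags)
    return cells


_METRICS = {
    "whole_cell": lambda c: c.whole_cell_count,
    "nuclear": lambda c: c.nuclear_count,
    "cytoplasmic": lambda c: c.cytoplasmic_count,
    "foci_per_nucleus": lambda c: c.nuclear_count,  # gamma-H2AX convention
}


def cells_to_frame(
    cells: dict[tuple[str, str], list[CellQuant]], metric: str = "nuclear"
) -> pd.DataFrame:
    """Tidy per-cell table from ``{(condition, experiment): [CellQuant]}``.

    Excluded cells are dropped here, before any averaging.
    """
    fn = _METRICS[metric]
    rows = [
        {"condition": cond, "experiment": exp, "value": fn(c)}
        for (cond, exp), cc in cells.items()
        for c in cc
        if not c.excluded
    ]
    return pd.DataFrame(rows, columns=["condition", "experiment", "value"])


def summarize_condition(
    frame: pd.DataFrame, nt_label: str = "NT", metric: str = "nuclear"
) -> list[ConditionSummary]:
    """Condition summaries with experiment-level averaging.

    Cells are averaged within each (condition, experiment) first; the
    across-experiment mean ± SD of those per-experiment means is reported,
    together with the fold change versus NT and the NT-corrected delta.
    A zero NT mean leaves the fold change undefined (reported missing).
    """
    if nt_label not in set(frame["condition"]):
        raise FociQuantError(f"untreated condition {nt_label!r} absent from the data")
    per_exp = frame.groupby(["condition", "experiment"])["value"].mean()
    nt_means = per_exp.loc[nt_label]
    nt_mean = float(nt_means.mean())
    out = []
    for cond in frame["condition"].unique():
        means = per_exp.loc[cond]
        mean = float(means.mean())
        sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
        if nt_mean == 0.0:
            fold = None
            warnings.warn(
                f"NT mean is 0: fold change undefined for {cond!r}", stacklevel=2
            )
        else:
            fold = mean / nt_mean
        out.append(
            ConditionSummary(
                condition=str(cond),
                metric=metric,
                per_experiment_means={str(e): float(v) for e, v in means.items()},
                mean=mean,
                sd=sd,
                fold_change=fold,
                delta=mean - nt_mean,
                n_cells=int((frame["condition"] == cond).sum()),
            )
        )
    return out
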