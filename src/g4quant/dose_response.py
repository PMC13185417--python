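"""Curve-shaped readouts: viability IC50, apparent-KD titrations, FRET melting.

All three assays reduce to one of two primitives:

* a four-parameter logistic (4PL) fitted on log-dose, whose midpoint is
  reported as IC50 (viability) or apparent KD (binding), and
* a min-max-normalised melting curve whose half-transition temperature
  T1/2 is read off by interpolation, with ligand effects expressed as
  differences ΔT1/2 and ΔΔT1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "MeltResult",
    "MeltComparison",
    "four_param_logistic",
    "normalize_viability",
    "fit_4pl",
    "fit_fqa",
    "normalize_melt",
    "compute_t_half",
    "delta_t_half",
    "delta_delta_t_half",
]


class DoseResponseError(ValueError):
    pass


def four_param_logistic(
    dose: np.ndarray,
    bottom: float,
    top: float,
    mid: float,
    hill: float,
    direction: str = "descending",
) -> np.ndarray:
    """Four-parameter logistic response as a function of dose.

    ``descending``: response falls from ``top`` (dose → 0) to ``bottom``
    (dose → ∞), crossing the half-range at ``mid`` — the shape of a
    viability or quenching curve. ``ascending`` is the mirror image.
    ``hill`` > 0 controls steepness in log-dose.
    """
    dose = np.asarray(dose, dtype=float)
    ratio = np.divide(dose, mid, out=np.zeros_like(dose), where=mid > 0)
    if direction == "descending":
        return bottom + (top - bottom) / (1.0 + ratio**hill)
    if direction == "ascending":
        return top + (bottom - top) / (1.0 + ratio**hill)
    raise DoseResponseError(f"unknown direction {direction!r}")


@dataclass
class DoseResponseFit:
    """A fitted 4PL curve; ``mid`` is IC50 or apparent KD depending on assay."""

    mid: float
    hill: float
    top: float
    bottom: float
    mid_se: float
    hill_se: float
    top_se: float
    bottom_se: float
    converged: bool
    n_points: int
    direction: str = "descending"
    unit: str = ""
    label: str = "mid"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mid <= 0:
            raise DoseResponseError("fitted midpoint must be positive")
        if self.bottom > self.top:
            raise DoseResponseError("bottom must not exceed top")

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return four_param_logistic(
            dose, self.bottom, self.top, self.mid, self.hill, self.direction
        )


def normalize_viability(table: pd.DataFrame, nt_label: str = "NT") -> pd.DataFrame:
    """Convert absorbance to percent viability relative to untreated wells.

    ``table`` needs columns ``condition`` and ``absorbance`` (one value per
    well, already averaged over the absorbance window). Viability is
    ``100 x absorbance / mean(NT absorbance)``, so the NT mean is 100 by
    construction.
    """
    nt = table.loc[table["condition"] == nt_label, "absorbance"]
    if len(nt) < 2:
        raise DoseResponseError(f"need >= 2 untreated ({nt_label!r}) wells, got {len(nt)}")
    nt_mean = float(nt.mean())
    if nt_mean <= 0:
        raise DoseResponseError("untreated mean absorbance must be positive")
    out = table.copy()
    out["viability_pct"] = 100.0 * out["absorbance"] / nt_mean
    return out


def _fit_core(
    dose: np.ndarray, response: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray, bool, list[str]]:
    """Least-squares 4PL fit on log10(dose). Returns (params, SEs, converged, warnings)."""
    logd = np.log10(dose)

    def model(logx, bottom, top, logmid, hill):
        return four_param_logistic(10.0**logx, bottom, top, 10.0**logmid, hill, direction)

    lo, hi = float(response.min()), float(response.max())
    # midpoint initialised from the dose whose response is nearest half-range
    half = 0.5 * (lo + hi)
    logmid0 = logd[int(np.argmin(np.abs(response - half)))]
    p0 = [lo, hi, logmid0, 1.0]
    bounds = (
        [-np.inf, -np.inf, logd.min() - 1.0, 0.1],
        [np.inf, np.inf, logd.max() + 1.0, 10.0],
    )
    msgs: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, logd, response, p0=p0, bounds=bounds, maxfev=20000)
        converged = np.all(np.isfinite(popt))
    except RuntimeError as exc:  # non-convergence: report best iterate via a relaxed fit
        msgs.append(f"non-convergence: {exc}")
        popt, pcov = np.array(p0), np.full((4, 4), np.nan)
        converged = False
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    return popt, ses, converged, msgs


def fit_4pl(
    dose: np.ndarray,
    response: np.ndarray,
    direction: str = "descending",
    unit: str = "",
    label: str = "mid",
) -> DoseResponseFit:
    """Fit a four-parameter dose-response curve on log10(dose).

    Requires at least 5 distinct positive doses. The fitted midpoint is the
    relative IC50/KD (the inflection of the 4PL), following the usual
    GraphPad-style convention. Constant responses are rejected as carrying
    no dose dependence; non-convergence is flagged, not raised.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose.shape != response.shape:
        raise DoseResponseError("dose and response must have equal length")
    if np.any(dose <= 0):
        raise DoseResponseError("doses must be strictly positive (drop zero-dose wells)")
    if not np.all(np.isfinite(response)):
        raise DoseResponseError("responses must be finite")
    if len(np.unique(dose)) < 5:
        raise DoseResponseError("need >= 5 distinct doses for a 4PL fit")
    if np.allclose(response, response[0]):
        raise DoseResponseError("no dose dependence: responses are constant")

    popt, ses, converged, msgs = _fit_core(dose, response, direction)
    bottom, top, logmid, hill = popt
    if bottom > top:  # reparametrise so bottom <= top always holds
        bottom, top = top, bottom
        ses[0], ses[1] = ses[1], ses[0]
    mid = 10.0**logmid
    # delta-method SE for mid from the SE of log10(mid)
    mid_se = float(mid * np.log(10.0) * ses[2]) if np.isfinite(ses[2]) else float("nan")
    return DoseResponseFit(
        mid=float(mid),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        mid_se=mid_se,
        hill_se=float(ses[3]),
        top_se=float(ses[1]),
        bottom_se=float(ses[0]),
        converged=bool(converged),
        n_points=int(len(dose)),
        direction=direction,
        unit=unit,
        label=label,
        warnings=msgs,
    )


_FQA_COLUMNS = ("dose", "unit", "F_T0", "F_T60")


def fit_fqa(table: pd.DataFrame, mode: str = "classical") -> DoseResponseFit:
    """Apparent-KD fit from a fluorescence-quenching titration.

    ``classical``: a labelled G4 oligonucleotide is held fixed and the ligand
    titrated; binding quenches the dye. ``reverse``: the (intrinsically
    fluorescent) ligand is held fixed and the labelled oligonucleotide
    titrated. In both cases the per-well response is the fraction of the
    pre-incubation fluorescence remaining after 60 min (``F_T60 / F_T0``,
    in percent), which cancels well-to-well loading differences, and the
    4PL midpoint of that response versus dose is the apparent KD.
    """
    if mode not in ("classical", "reverse"):
        raise DoseResponseError(f"unknown FQA mode {mode!r}")
    missing = [c for c in _FQA_COLUMNS if c not in table.columns]
    if missing:
        raise DoseResponseError(f"FQA table missing columns: {missing}")
    if (table["F_T0"] <= 0).any():
        raise DoseResponseError("F_T0 must be positive in every well")
    treated = table[table["dose"] > 0]
    response = 100.0 * treated["F_T60"].to_numpy() / treated["F_T0"].to_numpy()
    unit = str(treated["unit"].iloc[0]) if len(treated) else ""
    return fit_4pl(
        treated["dose"].to_numpy(),
        response,
        direction="descending",
        unit=unit,
        label="appKD",
    )


# --------------------------------------------------------------------- melting

@dataclass
class MeltResult:
    """A min-max-normalised melting curve (0-100%) with its T1/2."""

    temperature_c: np.ndarray
    emission_pct: np.ndarray
    t_half_c: float
    protocol: str = "classical"

    def __post_init__(self) -> None:
        tmin, tmax = float(self.temperature_c.min()), float(self.temperature_c.max())
        if not (tmin <= self.t_half_c <= tmax):
            raise DoseResponseError("T1/2 outside the measured temperature range")


@dataclass
class MeltComparison:
    """ΔT1/2 (ligand-induced shift) and optionally ΔΔT1/2 (competitor effect)."""

    delta_t_half_c: float
    delta_delta_t_half_c: float | None = None
    protocol: str = "classical"


def normalize_melt(table: pd.DataFrame, ramp: str = "heating") -> pd.DataFrame:
    """Min-max normalise reporter emission to 0-100% over the heating ramp.

    ``table`` needs columns ``temperature_C`` and ``emission``; an optional
    ``ramp`` column restricts the analysis to the stepwise temperature
    increase (the cooling ramp, when present, is ignored). Normalisation is
    invariant to positive affine rescaling of the raw signal.
    """
    if "ramp" in table.columns:
        table = table[table["ramp"] == ramp]
    if len(table) < 20:
        raise DoseResponseError("need >= 20 temperature points spanning the transition")
    table = table.sort_values("temperature_C").reset_index(drop=True)
    em = table["emission"].to_numpy(dtype=float)
    lo, hi = em.min(), em.max()
    if hi == lo:
        raise DoseResponseError("constant emission: no melting transition")
    out = table.copy()
    out["emission_pct"] = 100.0 * (em - lo) / (hi - lo)
    return out


def compute_t_half(
    normalized: pd.DataFrame, smooth: bool = True, protocol: str = "classical"
) -> MeltResult:
    """Half-transition temperature from a normalised melting curve.

    T1/2 is the temperature of the first upward crossing of 50% emission on
    the heating ramp, linearly interpolated between the two bracketing
    points. A 3-point running median (on by default) suppresses spurious
    crossings from point noise.
    """
    temp = normalized["temperature_C"].to_numpy(dtype=float)
    em = normalized["emission_pct"].to_numpy(dtype=float)
    order = np.argsort(temp)
    temp, em = temp[order], em[order]
    if smooth and len(em) >= 3:
        sm = em.copy()
        sm[1:-1] = np.median(np.column_stack([em[:-2], em[1:-1], em[2:]]), axis=1)
        em = sm
    crossings = np.nonzero((em[:-1] < 50.0) & (em[1:] >= 50.0))[0]
    if len(crossings) == 0:
        if em[0] >= 50.0 and np.any(em < 50.0):
            raise DoseResponseError("curve starts above 50%: transition outside range")
        raise DoseResponseError("transition outside range: no 50% crossing")
    i = int(crossings[0])
    frac = (50.0 - em[i]) / (em[i + 1] - em[i])
    t_half = temp[i] + frac * (temp[i + 1] - temp[i])
    return MeltResult(
        temperature_c=temp, emission_pct=em, t_half_c=float(t_half), protocol=protocol
    )


def _check_same_grid(a: MeltResult, b: MeltResult) -> None:
    if a.temperature_c.shape != b.temperature_c.shape or not np.allclose(
        a.temperature_c, b.temperature_c
    ):
        raise DoseResponseError("melting curves measured on different temperature grids")
    if a.protocol != b.protocol:
        raise DoseResponseError(
            f"melting curves from different protocols: {a.protocol!r} vs {b.protocol!r}"
        )


def delta_t_half(with_ligand: MeltResult, dna_alone: MeltResult) -> MeltComparison:
    """Ligand-induced thermal stabilisation: T1/2(DNA+ligand) - T1/2(DNA)."""
    _check_same_grid(with_ligand, dna_alone)
    return MeltComparison(
        delta_t_half_c=with_ligand.t_half_c - dna_alone.t_half_c,
        protocol=with_ligand.protocol,
    )


def delta_delta_t_half(
    with_competitor: tuple[MeltResult, MeltResult],
    without_competitor: tuple[MeltResult, MeltResult],
) -> MeltComparison:
    """Competitor effect on stabilisation: ΔT1/2(with) - ΔT1/2(without).

    Each argument is a ``(DNA+ligand, DNA alone)`` pair measured under one
    competitor condition with a shared temperature protocol.
    """
    d_with = delta_t_half(*with_competitor)
    d_without = delta_t_half(*without_competitor)
    if d_with.protocol != d_without.protocol:
        raise DoseResponseError("ΔΔT1/2 requires a shared melting protocol")
    return MeltComparison(
        delta_t_half_c=d_with.delta_t_half_c,
        delta_delta_t_half_c=d_with.delta_t_half_c - d_without.delta_t_half_c,
        protocol=d_with.protocol,
    )
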