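"""Bliss-independence scoring of drug-pair viability matrices.

Under Bliss independence two drugs act through independent mechanisms, so
the expected combined inhibition is ``fA + fB - fA*fB``. The per-pair score
is the observed excess over this expectation, in percentage points; pairs
scoring above +10 are conventionally called synergistic. For foci-based
readouts the analogous comparison is against the simple additive
expectation of the NT-corrected single-agent deltas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynergyMatrix",
    "FociSynergyResult",
    "SYNERGY_SCORE_THRESHOLD",
    "bliss_expected",
    "bliss_score_matrix",
    "additional_lethality",
    "foci_additive_comparison",
    "synergy_report",
]

#: a dose pair is called synergistic when its Bliss excess exceeds this
SYNERGY_SCORE_THRESHOLD = 10.0


class SynergyError(ValueError):
    pass


def bliss_expected(inhibition_a, inhibition_b):
    """Bliss-independence expected combined inhibition, fA + fB - fA*fB.

    Accepts scalars or arrays of inhibition fractions in [0, 1] (values
    within 1e-9 of the bounds are clipped).
    """
    fa = np.asarray(inhibition_a, dtype=float)
    fb = np.asarray(inhibition_b, dtype=float)
    for f, name in ((fa, "inhibition_a"), (fb, "inhibition_b")):
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise SynergyError(f"{name} outside [0, 1]")
    fa, fb = np.clip(fa, 0.0, 1.0), np.clip(fb, 0.0, 1.0)
    out = fa + fb - fa * fb
    return float(out) if out.ndim == 0 else out


@dataclass
class SynergyMatrix:
    """Scored dose-pair viability grid.

    ``viability`` and ``score`` are wide DataFrames indexed by dose of drug
    A (rows) and dose of drug B (columns), zero-dose margins included;
    scores are defined on combination cells only (NaN on margins).
    ``mean_score`` averages combination cells.
    """

    viability: pd.DataFrame
    score: pd.DataFrame
    mean_score: float
    synergistic: pd.DataFrame
    replicates: int
    unit_a: str = ""
    unit_b: str = ""
    n_clipped: int = 0
    threshold: float = SYNERGY_SCORE_THRESHOLD

    def combination_scores(self) -> np.ndarray:
        vals = self.score.to_numpy(dtype=float)
        return vals[np.isfinite(vals)]


def bliss_score_matrix(
    table: pd.DataFrame, threshold: float = SYNERGY_SCORE_THRESHOLD
) -> SynergyMatrix:
    """Score a long-format viability matrix against Bliss independence.

    ``table`` columns: dose_a, dose_b, replicate, viability_pct (plus
    optional unit columns). Replicates are averaged per dose pair first;
    viability is clipped to [0, 100] before conversion to inhibition
    fractions. Monotherapy rows/columns (dose 0) define the expectation:
    score(a, b) = 100 x [f_obs(a, b) - bliss(f(a, 0), f(0, b))].
    """
    required = {"dose_a", "dose_b", "viability_pct"}
    missing = required - set(table.columns)
    if missing:
        raise SynergyError(f"matrix table missing columns: {sorted(missing)}")
    replicates = int(table["replicate"].nunique()) if "replicate" in table.columns else 1
    unit_a = str(table["unit_a"].iloc[0]) if "unit_a" in table.columns else ""
    unit_b = str(table["unit_b"].iloc[0]) if "unit_b" in table.columns else ""

    n_clipped = int(((table["viability_pct"] < 0) | (table["viability_pct"] > 100)).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} wells clipped to [0, 100] %", stacklevel=2)
    clipped = table.assign(viability_pct=table["viability_pct"].clip(0.0, 100.0))
    wide = (
        clipped.groupby(["dose_a", "dose_b"])["viability_pct"].mean().unstack("dose_b")
    )
    if 0.0 not in wide.index or 0.0 not in wide.columns:
        raise SynergyError("matrix lacks zero-dose monotherapy margins")
    if wide.isna().any().any():
        raise SynergyError("viability matrix has missing dose pairs")

    inhib = 1.0 - wide / 100.0
    fa = inhib.loc[:, 0.0]  # drug A alone, per dose of A
    fb = inhib.loc[0.0, :]  # drug B alone, per dose of B
    expected = pd.DataFrame(
        bliss_expected(fa.to_numpy()[:, None], fb.to_numpy()[None, :]),
        index=wide.index,
        columns=wide.columns,
    )
    score = 100.0 * (inhib - expected)
    # scores are meaningful on combination cells only
    score.loc[0.0, :] = np.nan
    score.loc[:, 0.0] = np.nan
    combo = score.to_numpy(dtype=float)
    mean_score = float(np.nanmean(combo))
    synergistic = score > threshold
    return SynergyMatrix(
        viability=wide,
        score=score,
        mean_score=mean_score,
        synergistic=synergistic,
        replicates=replicates,
        unit_a=unit_a,
        unit_b=unit_b,
        n_clipped=n_clipped,
        threshold=threshold,
    )


def additional_lethality(viability_pct):
    """Percentage of additional lethality relative to untreated cells.

    Defined as 100 - viability (%), floored at 0; preserves the shape of
    array or DataFrame input.
    """
    if isinstance(viability_pct, pd.DataFrame):
        return (100.0 - viability_pct).clip(lower=0.0)
    v = np.asarray(viability_pct, dtype=float)
    if not np.all(np.isfinite(v)):
        raise SynergyError("viability must be finite")
    out = np.clip(100.0 - v, 0.0, None)
    return float(out) if out.ndim == 0 else out


@dataclass
class FociSynergyResult:
    """Foci-based synergy: combination delta versus the additive expectation.

    Deltas are NT-corrected mean foci/nucleus. ``fold_beyond_additive`` is
    delta_combo / (delta_a + delta_b); 1 means purely additive, larger
    values indicate synergy. Undefined when the additive expectation is
    not positive.
    """

    delta_a: float
    delta_b: float
    delta_combo: float
    additive_expectation: float
    fold_beyond_additive: float | None
    beyond_additive: bool
    warnings: list[str] = field(default_factory=list)


def foci_additive_comparison(
    delta_combo: float, delta_a: float, delta_b: float
) -> FociSynergyResult:
    """Compare a combination's foci increase with the additive expectation."""
    additive = delta_a + delta_b
    msgs: list[str] = []
    if additive <= 0:
        msgs.append("additive expectation <= 0: fold undefined")
        warnings.warn(msgs[-1], stacklevel=2)
        fold = None
        beyond = False
    else:
        fold = delta_combo / additive
        beyond = fold > 1.0
    return FociSynergyResult(
        delta_a=float(delta_a),
        delta_b=float(delta_b),
        delta_combo=float(delta_combo),
        additive_expectation=float(additive),
        fold_beyond_additive=fold,
        beyond_additive=beyond,
        warnings=msgs,
    )


def synergy_report(
    matrix: SynergyMatrix,
    out_dir: str | Path,
    foci: FociSynergyResult | None = None,
    provenance: dict | None = None,
) -> dict[str, Path]:
    """Write a scored matrix as a CSV heatmap table plus a JSON summary.

    The JSON carries the matrix mean score, counts of pairs above the +10
    and +20 marks, the best pair, the optional foci comparison and a
    provenance block; keys are sorted so regeneration is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    score_csv = out_dir / "bliss_scores.csv"
    via_csv = out_dir / "viability.csv"
    matrix.score.to_csv(score_csv, float_format="%.6g")
    matrix.viability.to_csv(via_csv, float_format="%.6g")

    combo = matrix.combination_scores()
    if combo.size:
        flat = matrix.score.stack()
        best = flat.idxmax()
        best_pair = {
            "dose_a": float(best[0]),
            "dose_b": float(best[1]),
            "score": round(float(flat.max()), 6),
        }
    else:
        best_pair = None
    summary = {
        "mean_score": round(matrix.mean_score, 6),
        "n_pairs": int(combo.size),
        "n_pairs_score_gt_10": int((combo > 10.0).sum()),
        "n_pairs_score_gt_20": int((combo > 20.0).sum()),
        "best_pair": best_pair,
        "replicates": matrix.replicates,
        "units": {"a": matrix.unit_a, "b": matrix.unit_b},
        "n_clipped_wells": matrix.n_clipped,
        "provenance": provenance or {},
    }
    if foci is not None:
        summary["foci_comparison"] = {
            "delta_a": foci.delta_a,
            "delta_b": foci.delta_b,
            "delta_combo": foci.delta_combo,
            "additive_expectation": foci.additive_expectation,
            "fold_beyond_additive": foci.fold_beyond_additive,
            "beyond_additive": foci.beyond_additive,
        }
    summary_json = out_dir / "synergy_summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"scores": score_csv, "viability": via_csv, "summary": summary_json}
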