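#!/usr/bin/env python
"""Fit dose-response curves: SRB viability IC50 and FQA apparent KD.

Simulates an SRB viability titration (QN-302-like potency, low-nanomolar
IC50) and classical/reverse fluorescence-quenching titrations, fits the
4-parameter logistic to each, and writes the fitted parameters.

    python analysis/02_dose_response.py [--seed 1] [--out results/dose_response]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from g4quant.dose_response import fit_4pl, fit_fqa, normalize_viability
from g4quant.simulate import QN302_DOSES_NM, simulate_plate


def fit_to_dict(fit) -> dict:
    return {
        "label": fit.label,
        "mid": fit.mid,
        "mid_se": fit.mid_se,
        "hill": fit.hill,
        "top": fit.top,
        "bottom": fit.bottom,
        "unit": fit.unit,
        "n_points": fit.n_points,
        "converged": fit.converged,
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/dose_response"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    out = {}

    # SRB viability: 11-point half-log titration, 3 replicates, 5% CV
    srb_truth = {"bottom": 4.0, "top": 100.0, "mid": 4.2, "hill": 1.1, "unit": "nM"}
    plate = simulate_plate(
        "srb_viability", srb_truth, QN302_DOSES_NM, 0.05, 3, seed=int(rng.integers(2**31))
    )
    v = normalize_viability(plate)
    treated = v[v.dose > 0]
    srb_fit = fit_4pl(
        treated.dose.to_numpy(), treated.viability_pct.to_numpy(), unit="nM", label="IC50"
    )
    out["srb_ic50"] = {"true": srb_truth, "fit": fit_to_dict(srb_fit)}

    # FQA: classical (titrate ligand) and reverse (titrate oligonucleotide)
    for mode, kd in (("classical", 0.41), ("reverse", 0.35)):
        truth = {"bottom": 15.0, "top": 100.0, "mid": kd, "hill": 1.0, "unit": "uM"}
        tbl = simulate_plate(
            f"fqa_{mode}", truth, np.geomspace(0.006, 100.0, 12), 0.02, 2,
            seed=int(rng.integers(2**31)),
        )
        fit = fit_fqa(tbl, mode=mode)
        out[f"fqa_{mode}_app_kd"] = {"true": truth, "fit": fit_to_dict(fit)}

    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "fits.json"
    path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    for k, d in out.items():
        f = d["fit"]
        print(f"{k}: {f['label']} = {f['mid']:.3g} {f['unit']} (true {d['true']['mid']})")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
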