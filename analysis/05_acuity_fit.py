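#!/usr/bin/env python
"""Acuity thresholds of the synthetic eyes vs their Nyquist limits.

Fits the pooled 100-trial psychometric function per eye (threshold at 62.5%
correct, bootstrap CI), compares recovered thresholds with the generating
observers' true thresholds, and normalizes them to each eye's Nyquist limit.
Writes results/acuity_summary.csv.
"""

import json
from pathlib import Path

import pandas as pd

from foveolar import fit_psychometric, threshold_vs_nyquist
from foveolar import io as fio

import importlib.util

spec = importlib.util.spec_from_file_location(
    "drift_analysis", Path(__file__).with_name("04_drift_analysis.py"))
_mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(_mod)
load_landmarks = _mod.load_landmarks

ROOT = Path(__file__).resolve().parent.parent / "results"
SESSIONS = ROOT.parent / "scratch" / "sessions"


def main():
    rows = []
    for eye_dir in sorted(SESSIONS.iterdir()):
        trials = fio.read_trials_csv(eye_dir / "trials.csv")
        truth = json.loads((eye_dir / "truth.json").read_text())
        landmarks = load_landmarks(eye_dir / "landmarks.json")
        fit = fit_psychometric(trials, n_boot=500, seed=1)
        ratio, diff = threshold_vs_nyquist(fit, landmarks)
        rows.append({
            "eye": eye_dir.name,
            "true_threshold_arcsec": round(truth["observer_threshold_arcsec"], 1),
            "fit_threshold_arcsec": round(fit.threshold_arcsec, 1),
            "ci95_low": round(fit.ci95[0], 1),
            "ci95_high": round(fit.ci95[1], 1),
            "nyquist_arcsec": round(landmarks.nyquist_arcsec, 1),
            "threshold_over_nyquist": round(ratio, 2),
            "threshold_minus_nyquist_arcsec": round(diff, 1),
            "n_trials": fit.n_trials,
        })
        print(f"{eye_dir.name}: threshold {fit.threshold_arcsec:.1f} arcsec "
              f"[{fit.ci95[0]:.1f}, {fit.ci95[1]:.1f}] "
              f"(true {truth['observer_threshold_arcsec']:.1f}); Nyquist "
              f"{landmarks.nyquist_arcsec:.1f} arcsec -> ratio {ratio:.2f}")
    ROOT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "acuity_summary.csv", index=False)


if __name__ == "__main__":
    main()
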