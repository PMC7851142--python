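"""Simulation studies at the screen's study conditions.

Each function regenerates synthetic data from scratch, runs the full
pipeline and measures one operating characteristic: the null false-positive
rate of primary hit calling, recall of planted synergy, Bliss-surface
recovery, and EC50 estimation error.  Problem sizes default to 200
simulated screens of 100 genes (null) and 200 screens with planted
synergies (g = 0.8, b = 0.6, s = 0.5) — the conditions under which the
pipeline's power and calibration are characterised in docs/methods.md.
All randomness derives from a single seed via ``numpy.random.SeedSequence``
so paired noise levels reuse the same per-screen seeds (common random
numbers).
"""

from __future__ import annotations

import math

import numpy as np

from .dose_response import fit_4pl
from .hit_calling import call_duplexes, call_primary, concordance
from .scoring import score_screen
from .screen_data import ScreenDesign
from .simulate import (
    SimTruth,
    deviation_for_excess,
    evaluate_recovery,
    simulate_checkerboard,
    simulate_dose_response,
    simulate_screen,
)
from .synergy import analyze_checkerboard


def _screen_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def null_false_positive_rate(
    noise_cv: float, n_screens: int = 200, n_genes: int = 100, seed: int = 0
) -> float:
    """Fraction of no-interaction genes called primary hits at default thresholds."""
    design = ScreenDesign()
    fp = total = 0
    for s in _screen_seeds(seed, n_screens):
        truth = SimTruth.random(n_genes, n_synergy=0, noise_cv=noise_cv, seed=s)
        wells, _ = simulate_screen(None, truth, design)
        calls = call_primary(score_screen(wells, design))
        fp += int(calls["passed"].sum())
        total += len(calls)
    return fp / total


def synergy_recall(
    noise_cv: float = 0.05,
    n_screens: int = 200,
    n_genes: int = 30,
    n_synergy: int = 10,
    s: float = 0.5,
    seed: int = 0,
) -> float:
    """Recall of planted synergy (g=0.8, b=0.6) at primary thresholds."""
    design = ScreenDesign()
    tp = planted = 0
    for sd in _screen_seeds(seed, n_screens):
        truth = SimTruth.random(
            n_genes, n_synergy=n_synergy, s=s, noise_cv=noise_cv, seed=sd
        )
        wells, _ = simulate_screen(None, truth, design)
        calls = call_primary(score_screen(wells, design))
        rep = evaluate_recovery(truth, primary_calls=calls)
        tp += rep["primary_recall"] * n_synergy
        planted += n_synergy
    return tp / planted


def duplex_concordance_pattern(s: float = 0.5, seed: int = 0) -> dict:
    """Noiseless deconvolution of one planted-synergy gene.

    Returns the number of the four penetrance-laddered duplexes passing the
    secondary criteria and whether the 2-of-4 rule validates the gene.
    """
    design = ScreenDesign()
    truth = SimTruth(
        gene_effects={"GX": 0.8}, drug_effect=0.6, interaction={"GX": s},
        noise_cv=0.0, seed=seed,
    )
    wells, _ = simulate_screen(None, truth, design, layout="duplex")
    calls = call_duplexes(score_screen(wells, design))
    result = concordance(calls)
    return {
        "n_passing": int(result.loc[0, "n_duplexes_passing"]),
        "n_tested": int(result.loc[0, "n_duplexes_tested"]),
        "validated": bool(result.loc[0, "validated"]),
    }


def bliss_surface_recovery(seed: int = 0) -> dict:
    """Null and planted-excess recovery for synthetic checkerboards.

    Noiseless runs must recover zero excess and a planted +0.12 interior
    excess to numerical precision; the noisy run (CV 5%, 3 replicates)
    reports the recovered excess and its standard error at the planted cell.
    """
    import warnings

    kw = dict(ec50_a=80.0, hill_a=1.5, ec50_b=6.0, hill_b=1.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid0, _ = simulate_checkerboard(**kw, noise_cv=0.0, n_reps=1, seed=seed)
        null_surface = analyze_checkerboard(grid0)
        s_exp = 1.0 - null_surface.expected_effect[3, 3]
        dev = np.zeros_like(null_surface.excess)
        dev[3, 3] = deviation_for_excess(0.12, s_exp)
        gridp, _ = simulate_checkerboard(
            **kw, bliss_deviation=dev, noise_cv=0.0, n_reps=1, seed=seed
        )
        planted_surface = analyze_checkerboard(gridp)
    gridn, _ = simulate_checkerboard(
        **kw, bliss_deviation=dev, noise_cv=0.05, n_reps=3, seed=seed
    )
    noisy = analyze_checkerboard(gridn)
    se = float(noisy.per_cell_sd[3, 3] / math.sqrt(gridn.n_reps))
    return {
        "null_max_abs_excess": float(np.abs(null_surface.excess).max()),
        "planted_excess_noiseless": float(planted_surface.excess[3, 3]),
        "planted_excess_noisy": float(noisy.excess[3, 3]),
        "planted_excess_se": se,
    }


def ec50_recovery_error(
    n_sim: int = 200, noise_cv: float = 0.05, n_doses: int = 8, n_reps: int = 3,
    ec50: float = 80.0, hill: float = 1.5, seed: int = 0,
) -> float:
    """Median |log2(EC50_est / EC50_true)| over repeated noisy 4PL fits."""
    errors = []
    for s in _screen_seeds(seed, n_sim):
        doses, resp = simulate_dose_response(
            ec50=ec50, hill=hill, noise_cv=noise_cv, n_doses=n_doses,
            n_reps=n_reps, seed=s,
        )
        fit = fit_4pl(doses, resp, seed=s)
        errors.append(abs(math.log2(fit.ec50 / ec50)))
    return float(np.median(errors))
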