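"""Standard synthetic benchmarks for the decoding pipeline.

Two study conditions, each run over 20 independently seeded sessions:

* **recovery** — 40 channels × 6 bands (240 candidate features), 100 task
  trials, five informative channel×band pairs on distinct channels with
  effect sizes chosen so that ordinary least squares on the five ground-truth
  feature columns gives an in-sample R² near 0.6.  Measures whether the
  pipeline finds the informative pairs and decodes speed on held-out trials.
* **null** — the same generator with no informative pairs.  Measures the
  false-selection behaviour and the chance level of the test-set metrics.

The stability loop runs 25 iterations per session here (the single-session
default elsewhere is 100) to keep the 20-session sweep tractable on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stability
from .pipeline import run_decoding_pipeline
from .synthetic import SimulationConfig, generate_session

RECOVERY_PAIRS = (
    (3, "theta", 0.45),
    (11, "alpha", 0.45),
    (17, "beta", 0.45),
    (23, "low_gamma", 0.45),
    (31, "high_gamma", 0.45),
)

N_SEEDS = 20
N_STABILITY = 25


def benchmark_config(seed: int, informative: bool = True) -> SimulationConfig:
    return SimulationConfig(
        n_channels=40,
        n_trials=100,
        informative_pairs=RECOVERY_PAIRS if informative else (),
        rng_seed=seed,
    )


def _session_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def ground_truth_ols_r2(bundle, result) -> float:
    """In-sample R² of OLS on the true informative feature columns — the
    independent check that the generator produced the intended signal
    strength, before any selection machinery runs."""
    fm = result.feature_matrix
    y = np.array(bundle.ground_truth["normalized_speed"])[
        result.speed_table["trial_id"]]
    ids = [f"{p['channel']}|{p['band']}"
           for p in bundle.ground_truth["informative_pairs"]]
    idx = [fm.feature_ids.index(i) for i in ids]
    A = np.column_stack([np.ones(len(y)), fm.values[:, idx]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(1 - resid.var() / y.var())


def intercept_only_accuracy(result) -> float:
    """Decoded accuracy of the intercept-only model (the base-rate floor)."""
    test = result.test_idx
    st = result.speed_table
    y_train = st["normalized_speed"].to_numpy()[result.train_idx]
    const = np.full(len(test), y_train.mean())
    return stability.decoded_accuracy(
        const, result.speed_norm,
        st["instruction"].to_numpy()[test],
        st["actual_outcome"].to_numpy()[test])


def run_recovery_benchmark(master_seed: int = 0, n_seeds: int = N_SEEDS,
                           n_stability: int = N_STABILITY,
                           progress: bool = False) -> pd.DataFrame:
    """Per-seed recovery results; one row per session seed."""
    rows = []
    true_ids = {f"ch{c:02d}|{b}" for c, b, _ in RECOVERY_PAIRS}
    for i, seed in enumerate(_session_seeds(master_seed, n_seeds)):
        bundle = generate_session(benchmark_config(seed, informative=True))
        res = run_decoding_pipeline(bundle, seed=seed, n_stability=n_stability)
        ft = res.stability_report.feature_table.sort_values(
            ["selection_fraction", "feature_id"], ascending=[False, True],
            kind="mergesort")
        top8 = set(ft.head(8)["feature_id"])
        rows.append({
            "seed": seed,
            "T_n": len(res.speed_table),
            "test_R": res.test_metrics.R,
            "test_MSE": res.test_metrics.MSE,
            "accuracy": res.test_accuracy,
            "floor_accuracy": intercept_only_accuracy(res),
            "n_selected": len(res.model.selected_ids),
            "true_in_final": len(true_ids & set(res.model.selected_ids)),
            "true_in_top8": len(true_ids & top8),
            "gt_ols_r2": ground_truth_ols_r2(bundle, res),
            "stability_R_mean": res.stability_report.summary()["R_mean"],
        })
        if progress:
            print(f"  recovery session {i + 1}/{n_seeds}: "
                  f"R={rows[-1]['test_R']:.3f} "
                  f"true_in_final={rows[-1]['true_in_final']}", flush=True)
    return pd.DataFrame(rows)


def run_null_benchmark(master_seed: int = 0, n_seeds: int = N_SEEDS,
                       n_stability: int = 0,
                       progress: bool = False) -> pd.DataFrame:
    """Per-seed null-control results (no informative pairs)."""
    rows = []
    for i, seed in enumerate(_session_seeds(master_seed + 10_000, n_seeds)):
        bundle = generate_session(benchmark_config(seed, informative=False))
        res = run_decoding_pipeline(bundle, seed=seed, n_stability=n_stability)
        r = res.test_metrics.R
        rows.append({
            "seed": seed,
            "T_n": len(res.speed_table),
            "test_R": r,
            # an intercept-only model decodes no linear relationship: |R| = 0
            "abs_test_R": abs(r) if np.isfinite(r) else 0.0,
            "test_MSE": res.test_metrics.MSE,
            "accuracy": res.test_accuracy,
            "floor_accuracy": intercept_only_accuracy(res),
            "n_selected": len(res.model.selected_ids),
        })
        if progress:
            print(f"  null session {i + 1}/{n_seeds}: "
                  f"|R|={rows[-1]['abs_test_R']:.3f} "
                  f"n_selected={rows[-1]['n_selected']}", flush=True)
    return pd.DataFrame(rows)


def recovery_summary(df: pd.DataFrame) -> dict:
    r = df["test_R"].to_numpy()
    return {
        "median_test_R": float(np.median(r[np.isfinite(r)])),
        "frac_seeds_ge4_true": float((df["true_in_final"] >= 4).mean()),
        "median_true_in_top8": float(df["true_in_top8"].median()),
        "median_gt_ols_r2": float(df["gt_ols_r2"].median()),
        "median_accuracy": float(df["accuracy"].median()),
        "n_seeds": int(len(df)),
    }


def null_summary(df: pd.DataFrame) -> dict:
    absr = df["abs_test_R"].to_numpy()
    return {
        "median_abs_test_R": float(np.median(absr[np.isfinite(absr)])),
        "median_n_selected": float(df["n_selected"].median()),
        "median_accuracy": float(df["accuracy"].median()),
        "median_floor_accuracy": float(df["floor_accuracy"].median()),
        "median_accuracy_minus_floor": float(
            (df["accuracy"] - df["floor_accuracy"]).median()),
        "n_seeds": int(len(df)),
    }
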