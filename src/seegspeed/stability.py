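"""Stability analysis over repeated CV partitions and test-set evaluation.

The cross-validated selection procedure is repeated ``n_iter`` times (100 by
default) with re-randomised 10-fold partitions of one fixed training set,
keeping the test set the same.  Each iteration yields a λ̂, per-fold support
sets at λ̂, a final selected set from the full training set, an unpenalised
refit, and test metrics (Pearson R, MSE, decoded categorical accuracy).  A
feature's selection fraction is the number of fold fits in which it received
a nonzero coefficient divided by the number of fold fits in which it was a
candidate (folds × iterations).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior
from .bands import BAND_ORDER
from .behavior import SpeedNormalization
from .decoder import DecodingModel, cross_validate_lambda, fit_decoding_model

logger = logging.getLogger(__name__)


class StabilityError(ValueError):
    pass


@dataclass
class Metrics:
    R: float  # Pearson correlation actual vs predicted (nan if undefined)
    MSE: float
    accuracy: float | None = None


@dataclass
class StabilityReport:
    feature_table: pd.DataFrame  # per feature: counts and selection_fraction
    per_iteration: pd.DataFrame  # λ̂, n_selected, R, MSE, accuracy
    band_proportions: dict
    hemisphere_summary: dict
    handedness: str
    n_iter: int
    k_folds: int

    def summary(self) -> dict:
        """Mean ± sample sd of the per-iteration test metrics (R̄, MSĒ, accuracy)."""
        it = self.per_iteration
        out = {}
        for col in ("R", "MSE", "accuracy"):
            vals = it[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            out[f"{col}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
            out[f"{col}_sd"] = (float(np.std(vals, ddof=1))
                                if vals.size > 1 else float("nan"))
        return out


def evaluate(model: DecodingModel, X_test: np.ndarray, y_test: np.ndarray) -> Metrics:
    """Pearson R and MSE of the model on held-out trials.

    ``X_test`` holds all candidate features (columns aligned to the training
    matrix); an intercept-only model has zero-variance predictions and R is
    reported as nan with a warning.
    """
    y_test = np.asarray(y_test, float)
    if len(y_test) < 3:
        raise StabilityError(f"need at least 3 test trials, got {len(y_test)}")
    y_hat = model.predict(X_test)
    mse = float(np.mean((y_test - y_hat) ** 2))
    if np.std(y_hat) == 0 or np.std(y_test) == 0:
        logger.warning("zero-variance predictions; Pearson R undefined")
        return Metrics(R=float("nan"), MSE=mse)
    r = float(np.corrcoef(y_test, y_hat)[0, 1])
    return Metrics(R=r, MSE=mse)


def decoded_accuracy(y_hat: np.ndarray, speed_norm: SpeedNormalization,
                     instructions, actual_outcomes) -> float:
    """Fraction of trials whose decoded categorical outcome matches the actual.

    Predictions are denormalised back to the [0, 1] ratio scale, classified
    with each trial's speed instruction, and compared with the actual
    outcomes (chance reference 0.5).
    """
    y_hat = np.asarray(y_hat, float)
    instructions = list(instructions)
    actual = list(actual_outcomes)
    if not (len(y_hat) == len(instructions) == len(actual)):
        raise StabilityError("prediction, instruction and outcome lengths differ")
    ratios = behavior.denormalize_speed(y_hat, speed_norm)
    decoded = [behavior.classify_outcome(r, i) for r, i in zip(ratios, instructions)]
    return float(np.mean([d == a for d, a in zip(decoded, actual)]))


def band_proportions(selected_bands) -> dict:
    """Multiset proportions of the six bands among selected features (sum 1)."""
    bands = list(selected_bands)
    if not bands:
        raise StabilityError("no selected features; band proportions undefined")
    n = len(bands)
    return {b: bands.count(b) / n for b in BAND_ORDER}


def hemisphere_summary(selected_hemispheres, handedness: str) -> dict:
    """Counts of selected features in the dominant vs non-dominant hemisphere.

    The dominant hemisphere is contralateral to the dominant hand: L for a
    right-handed subject, R for a left-handed one.
    """
    if handedness not in ("L", "R"):
        raise StabilityError(f"unknown handedness {handedness!r}")
    hemis = list(selected_hemispheres)
    if any(h not in ("L", "R") for h in hemis):
        raise StabilityError("missing or invalid hemisphere metadata")
    dominant_hemi = "L" if handedness == "R" else "R"
    dom = sum(h == dominant_hemi for h in hemis)
    return {"dominant": int(dom), "non_dominant": int(len(hemis) - dom)}


def run_stability(X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, y_test: np.ndarray,
                  feature_ids: list[str], feature_meta: pd.DataFrame,
                  speed_norm: SpeedNormalization,
                  test_instructions, test_outcomes,
                  handedness: str, n_iter: int = 100, k: int = 10,
                  rng: np.random.Generator | None = None,
                  variant: str = "combined") -> StabilityReport:
    """Repeat the CV selection procedure ``n_iter`` times on the fixed
    training set and evaluate each iteration's final model on the fixed test
    set."""
    if n_iter < 1:
        raise StabilityError("n_iter must be at least 1")
    rng = rng or np.random.default_rng()
    p = X_train.shape[1]
    times_selected = np.zeros(p, dtype=int)
    all_final_bands: list[str] = []
    all_final_hemis: list[str] = []
    rows = []
    for it in range(n_iter):
        cv = cross_validate_lambda(X_train, y_train, k=k, rng=rng)
        lam_idx = int(np.flatnonzero(cv.lambda_grid == cv.lambda_hat)[0])
        times_selected += cv.fold_nonzero[:, lam_idx, :].sum(axis=0)
        model = fit_decoding_model(X_train, y_train, cv.lambda_hat,
                                   feature_ids, speed_norm, variant=variant)
        metrics = evaluate(model, X_test, y_test)
        acc = decoded_accuracy(model.predict(X_test), speed_norm,
                               test_instructions, test_outcomes)
        sel_meta = feature_meta.iloc[model.selected_indices]
        all_final_bands.extend(sel_meta["band"])
        all_final_hemis.extend(sel_meta["hemisphere"])
        rows.append({
            "iteration": it,
            "lambda_hat": cv.lambda_hat,
            "n_selected": len(model.selected_indices),
            "selected": ";".join(model.selected_ids),
            "R": metrics.R,
            "MSE": metrics.MSE,
            "accuracy": acc,
        })
    times_sampled = n_iter * k
    feature_table = feature_meta.copy()
    feature_table.insert(0, "feature_id", feature_ids)
    feature_table["times_selected"] = times_selected
    feature_table["times_sampled"] = times_sampled
    feature_table["selection_fraction"] = times_selected / times_sampled
    props = (band_proportions(all_final_bands) if all_final_bands
             else {b: 0.0 for b in BAND_ORDER})
    hemi = (hemisphere_summary(all_final_hemis, handedness) if all_final_hemis
            else {"dominant": 0, "non_dominant": 0})
    return StabilityReport(
        feature_table=feature_table,
        per_iteration=pd.DataFrame(rows),
        band_proportions=props,
        hemisphere_summary=hemi,
        handedness=handedness,
        n_iter=n_iter,
        k_folds=k,
    )


def write_report(report: StabilityReport, out_dir) -> None:
    """stability.tsv + metrics.json + report.md, deterministically formatted.

    The feature table is sorted by selection fraction descending, ties broken
    by feature id; fractions are written with full round-trip precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ft = report.feature_table.sort_values(
        ["selection_fraction", "feature_id"], ascending=[False, True],
        kind="mergesort")
    ft.to_csv(out / "stability.tsv", sep="\t", index=False)
    payload = {
        "n_iterations": report.n_iter,
        "k_folds": report.k_folds,
        "handedness": report.handedness,
        "summary": report.summary(),
        "band_proportions": report.band_proportions,
        "hemisphere_summary": report.hemisphere_summary,
        "per_iteration": report.per_iteration.drop(columns=["selected"])
                               .to_dict(orient="records"),
    }
    with open(out / "metrics.json", "w") as f:
        json.dump(payload, f, indent=1, allow_nan=True)
    s = report.summary()
    top = ft.head(10)
    lines = [
        "# Stability report",
        "",
        f"{report.n_iter} iterations of {report.k_folds}-fold cross-validated "
        f"feature selection on a fixed training set; metrics on the fixed test set.",
        "",
        f"Test-set performance across iterations: R = {s['R_mean']:.3f} ± "
        f"{s['R_sd']:.3f}, MSE = {s['MSE_mean']:.3f} ± {s['MSE_sd']:.3f}, "
        f"decoded accuracy = {s['accuracy_mean']:.3f} ± {s['accuracy_sd']:.3f}.",
        "",
        "Band proportions of final selected features: "
        + ", ".join(f"{b}: {v:.4f}" for b, v in report.band_proportions.items()),
        "",
        f"Hemisphere (handedness {report.handedness}): "
        f"dominant {report.hemisphere_summary['dominant']}, "
        f"non-dominant {report.hemisphere_summary['non_dominant']}.",
        "",
        "Top features by selection fraction:",
        "",
        "| feature | region | hemisphere | selection fraction |",
        "|---|---|---|---|",
    ]
    for r in top.itertuples():
        lines.append(f"| {r.feature_id} | {r.region_label} | {r.hemisphere} | "
                     f"{r.selection_fraction:.4f} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")
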