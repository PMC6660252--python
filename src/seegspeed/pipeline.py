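"""End-to-end orchestration: session → spectrograms → features → decoder →
stability, with all randomness derived from one master seed."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior, decoder, features, spectral, stability


@dataclass
class PipelineResult:
    speed_table: pd.DataFrame
    speed_norm: behavior.SpeedNormalization
    feature_matrix: features.FeatureMatrix
    train_idx: np.ndarray
    test_idx: np.ndarray
    cv: decoder.CVResult
    model: decoder.DecodingModel
    test_metrics: stability.Metrics
    test_accuracy: float
    stability_report: stability.StabilityReport | None


def run_decoding_pipeline(bundle, spectral_config=None, variant: str = "combined",
                          seed: int = 0, n_stability: int = 100,
                          exclude_channels=(), k: int = 10,
                          spectrograms=None) -> PipelineResult:
    """Run the full decoding analysis for one session.

    ``n_stability=0`` skips the stability loop.  Precomputed ``spectrograms``
    may be passed to avoid repeating the CWT.
    """
    ss = np.random.SeedSequence(seed)
    split_rng, cv_rng, stab_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    if spectrograms is None:
        spectrograms = spectral.compute_session_spectrograms(
            bundle, spectral_config, exclude=exclude_channels)
    speed_table, speed_norm = behavior.build_trial_speed_table(bundle.trial_table)
    modeled = bundle.trial_table.set_index("trial_id").loc[speed_table["trial_id"]]
    modeled = modeled.reset_index()
    fm = features.build_feature_matrix(bundle, spectrograms, modeled, variant)

    y = speed_table["normalized_speed"].to_numpy()
    train, test = decoder.split_train_test(len(y), rng=split_rng)
    X_train, X_test = fm.values[train], fm.values[test]
    y_train, y_test = y[train], y[test]

    cv = decoder.cross_validate_lambda(X_train, y_train, k=k, rng=cv_rng)
    model = decoder.fit_decoding_model(X_train, y_train, cv.lambda_hat,
                                       fm.feature_ids, speed_norm, variant)
    metrics = stability.evaluate(model, X_test, y_test)
    instructions = speed_table["instruction"].to_numpy()[test]
    outcomes = speed_table["actual_outcome"].to_numpy()[test]
    accuracy = stability.decoded_accuracy(model.predict(X_test), speed_norm,
                                          instructions, outcomes)

    report = None
    if n_stability > 0:
        report = stability.run_stability(
            X_train, y_train, X_test, y_test, fm.feature_ids, fm.feature_meta,
            speed_norm, instructions, outcomes, bundle.handedness,
            n_iter=n_stability, k=k, rng=stab_rng, variant=variant)
    return PipelineResult(
        speed_table=speed_table, speed_norm=speed_norm, feature_matrix=fm,
        train_idx=train, test_idx=test, cv=cv, model=model,
        test_metrics=metrics, test_accuracy=accuracy, stability_report=report)
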