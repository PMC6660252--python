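"""Train the decoding model: 80/20 split, 10-fold CV λ search, LASSO
selection at λ̂, unpenalised refit, and test-set evaluation.

Reads features.tsv + modeled-trials.tsv (03_features.py) and writes
model.json and train-metrics.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from seegspeed import decoder, stability
from seegspeed.behavior import SpeedNormalization


def load_features(path):
    df = pd.read_csv(path, sep="\t")
    ids = ["|".join([c.split("|")[0], c.split("|")[3]])
           for c in df.columns[1:]]
    return df["trial_id"].to_numpy(), df.iloc[:, 1:].to_numpy(), ids


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", default="results/features_combined.tsv",
                    type=Path)
    ap.add_argument("--trials", default="results/modeled-trials.tsv",
                    type=Path)
    ap.add_argument("--variant", default="combined")
    ap.add_argument("--seed", default=0, type=int)
    ap.add_argument("--out-dir", default="results", type=Path)
    args = ap.parse_args()

    trial_ids, X, feature_ids = load_features(args.features)
    trials = pd.read_csv(args.trials, sep="\t").set_index("trial_id")
    trials = trials.loc[trial_ids]
    y = trials["normalized_speed"].to_numpy()
    logr = np.log(trials["speed_ratio"].to_numpy())
    norm = SpeedNormalization(log_mean=float(logr.mean()),
                              log_sd=float(logr.std(ddof=1)))

    ss = np.random.SeedSequence(args.seed)
    split_rng, cv_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    train, test = decoder.split_train_test(len(y), rng=split_rng)
    cv = decoder.cross_validate_lambda(X[train], y[train], rng=cv_rng)
    model = decoder.fit_decoding_model(X[train], y[train], cv.lambda_hat,
                                       feature_ids, norm, args.variant)
    metrics = stability.evaluate(model, X[test], y[test])
    acc = stability.decoded_accuracy(
        model.predict(X[test]), norm,
        trials["instruction"].to_numpy()[test],
        trials["actual_outcome"].to_numpy()[test])

    args.out_dir.mkdir(parents=True, exist_ok=True)
    decoder.save_model(model, args.out_dir / "model.json")
    payload = {"lambda_hat": cv.lambda_hat,
               "n_selected": len(model.selected_ids),
               "test_R": metrics.R, "test_MSE": metrics.MSE,
               "test_accuracy": acc,
               "n_train": int(len(train)), "n_test": int(len(test))}
    (args.out_dir / "train-metrics.json").write_text(
        json.dumps(payload, indent=1) + "\n")
    print(f"λ̂ = {cv.lambda_hat:.5g}; selected {len(model.selected_ids)} of "
          f"{X.shape[1]} features")
    print(f"test set ({len(test)} trials): R = {metrics.R:.3f}, "
          f"MSE = {metrics.MSE:.3f}, decoded accuracy = {acc:.3f}")


if __name__ == "__main__":
    main()
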