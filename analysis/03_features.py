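"""Build the trial × feature matrix of movement-window band power.

Reads the session directory and the spectrogram container, filters to
completed unperturbed trials, and writes modeled-trials.tsv plus one
features.tsv for the requested model variant.
"""

import argparse
from pathlib import Path

from seegspeed import behavior, features, session_io, spectral


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session", default="results/session", type=Path)
    ap.add_argument("--spectrograms", default="results/spectrograms.h5",
                    type=Path)
    ap.add_argument("--variant", default="combined",
                    choices=features.MODEL_VARIANTS)
    ap.add_argument("--out-dir", default="results", type=Path)
    args = ap.parse_args()

    bundle = session_io.read_session(args.session)
    spgs, _ = spectral.load_spectrograms(args.spectrograms)
    speed_table, norm = behavior.build_trial_speed_table(bundle.trial_table)
    modeled = bundle.trial_table.set_index("trial_id").loc[
        speed_table["trial_id"]].reset_index()
    fm = features.build_feature_matrix(bundle, spgs, modeled, args.variant)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    speed_table.to_csv(args.out_dir / "modeled-trials.tsv", sep="\t",
                       index=False)
    features.write_features_tsv(fm, args.out_dir / f"features_{args.variant}.tsv")
    print(f"T_n = {len(speed_table)} modeled trials; "
          f"J_n = {fm.n_features} candidate features ({args.variant}); "
          f"speed normalization: log_mean={norm.log_mean:.4f}, "
          f"log_sd={norm.log_sd:.4f}")


if __name__ == "__main__":
    main()
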