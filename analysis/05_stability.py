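"""Stability analysis: repeat the cross-validated selection over many
re-randomised fold partitions of the fixed training set and summarise
per-feature selection fractions, band proportions and hemisphere counts.

Runs from the session directory + spectrogram container (keeps the split
and test set fixed by the master seed) and writes stability.tsv,
metrics.json and report.md.
"""

import argparse
from pathlib import Path

from seegspeed import session_io, spectral, stability


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session", default="results/session", type=Path)
    ap.add_argument("--spectrograms", default="results/spectrograms.h5",
                    type=Path)
    ap.add_argument("--variant", default="combined")
    ap.add_argument("--iters", default=100, type=int)
    ap.add_argument("--seed", default=0, type=int)
    ap.add_argument("--out-dir", default="results/stability", type=Path)
    args = ap.parse_args()

    bundle = session_io.read_session(args.session)
    spgs, _ = spectral.load_spectrograms(args.spectrograms)
    from seegspeed.pipeline import run_decoding_pipeline
    res = run_decoding_pipeline(bundle, variant=args.variant, seed=args.seed,
                                n_stability=args.iters, spectrograms=spgs)
    stability.write_report(res.stability_report, args.out_dir)
    s = res.stability_report.summary()
    print(f"{args.iters} iterations: R = {s['R_mean']:.3f} ± {s['R_sd']:.3f}, "
          f"MSE = {s['MSE_mean']:.3f} ± {s['MSE_sd']:.3f}, "
          f"accuracy = {s['accuracy_mean']:.3f} ± {s['accuracy_sd']:.3f}")
    print("band proportions:",
          {k: round(v, 4) for k, v in
           res.stability_report.band_proportions.items()})
    print("hemisphere summary:", res.stability_report.hemisphere_summary,
          f"(handedness {bundle.handedness})")
    print(f"wrote stability.tsv / metrics.json / report.md to {args.out_dir}")


if __name__ == "__main__":
    main()
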