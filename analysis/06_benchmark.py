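"""Run the standard 20-session recovery and null benchmarks and write their
per-seed tables and summaries under results/benchmark/.

This is the same computation the acceptance script performs; expect ~15
minutes on one CPU at the default sizes.
"""

import argparse
import json
from pathlib import Path

from seegspeed import benchmark


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", default=0, type=int)
    ap.add_argument("--n-seeds", default=benchmark.N_SEEDS, type=int)
    ap.add_argument("--out-dir", default="results/benchmark", type=Path)
    args = ap.parse_args()

    args.out_dir.mkdir(parents=True, exist_ok=True)
    print(f"recovery benchmark ({args.n_seeds} sessions):", flush=True)
    rec = benchmark.run_recovery_benchmark(args.seed, n_seeds=args.n_seeds,
                                           progress=True)
    rec.to_csv(args.out_dir / "recovery.tsv", sep="\t", index=False)
    rsum = benchmark.recovery_summary(rec)
    print(json.dumps(rsum, indent=1))

    print(f"null benchmark ({args.n_seeds} sessions):", flush=True)
    null = benchmark.run_null_benchmark(args.seed, n_seeds=args.n_seeds,
                                        progress=True)
    null.to_csv(args.out_dir / "null.tsv", sep="\t", index=False)
    nsum = benchmark.null_summary(null)
    print(json.dumps(nsum, indent=1))

    (args.out_dir / "summary.json").write_text(
        json.dumps({"recovery": rsum, "null": nsum}, indent=1) + "\n")
    print(f"wrote tables and summary.json to {args.out_dir}")


if __name__ == "__main__":
    main()
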