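"""Notch-filter a session and compute z-scored log-power spectrograms.

Reads a session directory (01_simulate.py) and writes one HDF5 container of
per-channel spectrograms on the 50 ms bin grid.
"""

import argparse
from pathlib import Path

from seegspeed import session_io, spectral


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="session", default="results/session",
                    type=Path)
    ap.add_argument("--out", default="results/spectrograms.h5", type=Path)
    ap.add_argument("--exclude", default="",
                    help="comma-separated channel names to drop")
    args = ap.parse_args()

    bundle = session_io.read_session(args.session)
    exclude = tuple(c for c in args.exclude.split(",") if c)
    spgs = spectral.compute_session_spectrograms(bundle, exclude=exclude)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    spectral.save_spectrograms(spgs, args.out)
    first = next(iter(spgs.values()))
    print(f"wrote {len(spgs)} channel spectrograms to {args.out}: "
          f"{first.values.shape[0]} bins x {first.values.shape[1]} "
          f"frequencies ({first.freqs[0]:g}-{first.freqs[-1]:.1f} Hz)")


if __name__ == "__main__":
    main()
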