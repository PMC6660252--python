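"""Trial × feature matrices of band-averaged z-power over the movement window.

A feature is the mean z-scored log power of one channel over one frequency
band, averaged over the spectrogram bins whose label time falls inside
[MoveOnset, HitTarget] (inclusive).  Bands use half-open frequency intervals
[lo, hi), so shared printed edges (8, 15, 30, 60, 100 Hz) belong to the upper
band.  The combined model concatenates all six band matrices; column order is
channel-major, then band, and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BAND_ORDER, BandDefinition, get_band
from .spectral import Spectrogram

MODEL_VARIANTS = BAND_ORDER + ("combined",)


class FeatureError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    values: np.ndarray  # T_n × J_n
    feature_meta: pd.DataFrame  # channel, region_label, hemisphere, band
    trial_ids: np.ndarray
    model_variant: str

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return [f"{r.channel}|{r.band}" for r in self.feature_meta.itertuples()]


def extract_band_feature(spectrogram: Spectrogram, band: BandDefinition,
                         window: tuple[float, float]) -> float:
    """Mean z-power over in-band frequencies and in-window bins for one trial."""
    lo_t, hi_t = window
    tmask = (spectrogram.bin_times >= lo_t) & (spectrogram.bin_times <= hi_t)
    fmask = (spectrogram.freqs >= band.lo) & (spectrogram.freqs < band.hi)
    if not tmask.any():
        raise FeatureError(
            f"no spectrogram bins inside window [{lo_t:.3f}, {hi_t:.3f}]s "
            f"for band {band.name}")
    if not fmask.any():
        raise FeatureError(f"no analysis frequencies inside band {band.name}")
    return float(spectrogram.values[np.ix_(tmask, fmask)].mean())


def build_feature_matrix(bundle, spectrograms: dict[str, Spectrogram],
                         modeled_trials: pd.DataFrame,
                         variant: str = "combined") -> FeatureMatrix:
    """One row per modeled trial, one column per (channel, band) of the variant.

    ``spectrograms`` holds the retained (artifact-free) channels; channel
    order follows the bundle's channel table restricted to those names.
    """
    if variant not in MODEL_VARIANTS:
        raise FeatureError(
            f"unknown model variant {variant!r}; expected one of {MODEL_VARIANTS}")
    bands = BAND_ORDER if variant == "combined" else (variant,)
    channels = [n for n in bundle.channel_table["name"] if n in spectrograms]
    if not channels:
        raise FeatureError("no channels with spectrograms available")
    meta_by_name = bundle.channel_table.set_index("name")

    windows = list(zip(modeled_trials["move_onset"], modeled_trials["hit_target"]))
    cols, meta = [], []
    for ch in channels:
        spg = spectrograms[ch]
        for bname in bands:
            band = get_band(bname)
            col = np.empty(len(windows))
            for t, window in enumerate(windows):
                col[t] = extract_band_feature(spg, band, window)
            if not np.all(np.isfinite(col)):
                t_bad = int(np.flatnonzero(~np.isfinite(col))[0])
                raise FeatureError(
                    f"non-finite feature for trial "
                    f"{modeled_trials['trial_id'].iloc[t_bad]}, channel {ch}, "
                    f"band {bname}")
            cols.append(col)
            meta.append({
                "channel": ch,
                "region_label": meta_by_name.loc[ch, "region_label"],
                "hemisphere": meta_by_name.loc[ch, "hemisphere"],
                "band": bname,
            })
    return FeatureMatrix(
        values=np.column_stack(cols),
        feature_meta=pd.DataFrame(meta),
        trial_ids=modeled_trials["trial_id"].to_numpy(),
        model_variant=variant,
    )


def write_features_tsv(fm: FeatureMatrix, path) -> None:
    """features.tsv: trial_id, then one column per feature named
    channel|region|hemisphere|band."""
    headers = [f"{r.channel}|{r.region_label}|{r.hemisphere}|{r.band}"
               for r in fm.feature_meta.itertuples()]
    df = pd.DataFrame(fm.values, columns=headers)
    df.insert(0, "trial_id", fm.trial_ids)
    df.to_csv(path, sep="\t", index=False)
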