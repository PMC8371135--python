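#!/usr/bin/env python
"""Extract and fit receptive fields from the simulated recordings.

For every ROI: bar tuning curves from the OFF and ON protocols with
single-Gaussian and difference-of-Gaussians fits; a spatiotemporal receptive
field from the ternary noise by reverse correlation; and the spatiotemporal
frequency tuning map from the gratings. Writes a tidy fit table (one row per
ROI x polarity) and reports recovery of the ground-truth centers.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from t5rf import rf
from t5rf.preprocess import (
    RawRoiTrace,
    delta_f_over_f,
    epoch_and_resample,
    highpass_baseline,
)
from t5rf.stimuli import StimulusTrace


def load_traces(path):
    df = pd.read_csv(path)
    for (fly_id, roi_id), sub in df.groupby(["fly_id", "roi_id"]):
        yield RawRoiTrace(sub["time"].to_numpy(), sub["F"].to_numpy(),
                          roi_id=roi_id, fly_id=fly_id)


def load_noise_stimulus(events, in_dir):
    # the STRF needs the rendered noise field, which 01 stores as HDF5
    # alongside the events (the frames are random and not re-derivable from
    # the event table alone)
    import h5py

    with h5py.File(in_dir / "stimulus_ternary_noise.h5", "r") as f:
        return StimulusTrace(f["time_grid"][:], f["space_grid"][:],
                             f["contrast"][:], events,
                             orientation=f.attrs["orientation"],
                             pixel_width=f.attrs["pixel_width"])


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/rf_fits.csv"))
    args = ap.parse_args()

    truth = pd.read_csv(args.in_dir / "ground_truth.csv")
    rows = []
    for protocol, polarity in (("bars_off", "OFF"), ("bars_on", "ON")):
        events = pd.read_csv(args.in_dir / f"events_{protocol}.csv")
        for raw in load_traces(args.in_dir / f"traces_{protocol}.csv"):
            nt = delta_f_over_f(highpass_baseline(raw), events)
            tensor = epoch_and_resample(nt, events)
            curve = rf.bar_tuning_curve(tensor)
            gfit = rf.fit_gaussian(curve, r2_min=0.2)
            dfit = rf.fit_difference_of_gaussians(curve, r2_min=0.2)
            row = dict(fly_id=raw.fly_id, roi_id=raw.roi_id, polarity=polarity)
            if isinstance(gfit, rf.GaussianFit):
                row.update(A=gfit.A, x0=gfit.x0, w=gfit.w, fwhm=gfit.fwhm,
                           r2=gfit.r2, accepted=True)
            else:
                row.update(accepted=False, reject_reason=gfit.reason)
            if isinstance(dfit, rf.DoGFit):
                row.update(A_c=dfit.A_c, A_s=dfit.A_s, w_c=dfit.w_c,
                           w_s=dfit.w_s, dog_r2=dfit.r2)
            rows.append(row)
    fits = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fits.to_csv(args.out, index=False)

    ok = fits[fits["accepted"] & (fits["polarity"] == "OFF")]
    merged = ok.merge(truth[(truth.orientation == "vertical")],
                      on=["fly_id", "roi_id"], suffixes=("", "_true"))
    err = np.abs(merged["x0"] - merged["x0_true"])
    print(f"OFF fits accepted: {len(ok)}/{(fits['polarity'] == 'OFF').sum()}; "
          f"median |x0 - truth| = {err.median():.2f} deg")
    on_ok = fits[fits["accepted"] & (fits["polarity"] == "ON")]
    if len(on_ok) and len(ok):
        print(f"ON receptive fields are wider: median FWHM ON = "
              f"{on_ok['fwhm'].median():.1f} deg vs OFF = "
              f"{ok['fwhm'].median():.1f} deg")

    # spatiotemporal receptive fields from the ternary noise
    noise_events = pd.read_csv(args.in_dir / "events_ternary_noise.csv")
    noise = load_noise_stimulus(noise_events, args.in_dir)
    strf_rows = []
    for raw in load_traces(args.in_dir / "traces_ternary_noise.csv"):
        nt = delta_f_over_f(highpass_baseline(raw), noise_events)
        strf = rf.strf_reverse_correlation(nt, noise)
        row = dict(fly_id=raw.fly_id, roi_id=raw.roi_id)
        if isinstance(strf.spatial_fit, rf.GaussianFit):
            row.update(x0=strf.spatial_fit.x0, fwhm=strf.spatial_fit.fwhm,
                       r2=strf.spatial_fit.r2,
                       peak_lag_s=strf.lags[strf.peak_index[0]])
        strf_rows.append(row)
    strf_df = pd.DataFrame(strf_rows)
    strf_df.to_csv(args.out.parent / "strf_fits.csv", index=False)
    m = strf_df.dropna().merge(truth[truth.orientation == "vertical"],
                               on=["fly_id", "roi_id"], suffixes=("", "_true"))
    if len(m):
        print(f"STRF spatial slices: median |x0 - truth| = "
              f"{np.abs(m['x0'] - m['x0_true']).median():.2f} deg "
              f"({len(m)} ROIs)")

    # spatiotemporal frequency tuning from the gratings
    gr_events = pd.read_csv(args.in_dir / "events_gratings.csv")
    map_rows = []
    for raw in load_traces(args.in_dir / "traces_gratings.csv"):
        nt = delta_f_over_f(highpass_baseline(raw), gr_events)
        tensor = epoch_and_resample(nt, gr_events)
        fmap = rf.freq_tuning_map(tensor)
        for i, lam in enumerate(fmap.wavelengths):
            for j, tf in enumerate(fmap.temporal_freqs):
                map_rows.append(dict(fly_id=raw.fly_id, roi_id=raw.roi_id,
                                     wavelength=lam, temporal_freq=tf,
                                     amplitude=fmap.amplitudes[i, j]))
    pd.DataFrame(map_rows).to_csv(args.out.parent / "freq_maps.csv", index=False)
    print(f"frequency tuning maps written for "
          f"{len(map_rows) // 36} ROIs -> freq_maps.csv")


if __name__ == "__main__":
    main()
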