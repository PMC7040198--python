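"""Multiplex metric sensitivity: layer-count sweep of the time-varying
networks and the window-length sweep of node MCC.

Writes results/layer_count_sweep.tsv and results/window_length_mcc.tsv and
prints the qualitative behaviour (MPC saturates towards 1 with more
temporal layers; MCC barely moves).
"""

from __future__ import annotations

import pandas as pd

from _common import BETA, RESULTS, demo_cohort
from mxbrain.features import window_matrices
from mxbrain.mxmetrics import layer_count_sweep, window_length_sweep
from mxbrain.preprocess import bandpass


def main() -> None:
    cohort = demo_cohort(bands=(BETA,))
    fs = cohort.recordings[0].fs
    # 40 s of beta activity per subject -> 10 four-second windows
    subjects = [window_matrices(r.data, fs, BETA, window_s=4.0) for r in cohort]

    grid = list(range(2, 11))
    mpc = layer_count_sweep(subjects, grid, metric="mpc").rename(
        columns={"mean": "mpc_mean", "sd": "mpc_sd"}
    )
    mcc = layer_count_sweep(subjects, grid, metric="mcc").rename(
        columns={"mean": "mcc_mean", "sd": "mcc_sd"}
    )
    sweep = mpc.merge(mcc, on="n_layers")
    RESULTS.mkdir(exist_ok=True)
    sweep.to_csv(RESULTS / "layer_count_sweep.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(sweep.to_string(index=False))
    rel = (sweep.mcc_mean.max() - sweep.mcc_mean.min()) / sweep.mcc_mean.mean()
    print(f"MPC climbs from {sweep.mpc_mean.iloc[0]:.3f} (2 layers) to "
          f"{sweep.mpc_mean.iloc[-1]:.3f} (10 layers); "
          f"MCC varies only {100 * rel:.1f}% relative across the grid")

    rec = cohort.recordings[0]
    filt = bandpass(rec.data[:, : int(20 * fs)], fs, BETA)
    tables = window_length_sweep(filt, fs, lengths=[0.5, 1.0, 2.0, 4.0], metric="mcc")
    frame = pd.concat(
        [t.to_frame().assign(window_s=k) for k, t in tables.items()], ignore_index=True
    )
    frame.to_csv(RESULTS / "window_length_mcc.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(f"node MCC across window lengths written for subject {rec.subject_id}")


if __name__ == "__main__":
    main()
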