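"""Generate the synthetic film-watching study and persist its raw pieces.

Produces the embedding lexicon (word2vec text), the frame label table (TSV)
and the HFB recording with stimulus confounds (HDF5) under results/study/.
"""
from pathlib import Path

import numpy as np

from semenc import io, pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = pipeline.simulate_experiment(seed=SEED)
    io.write_lexicon(study.lexicon, OUT / "lexicon.vec")
    io.write_label_table(study.table, OUT / "frame_labels.tsv")
    io.write_recording(study.recording, OUT / "recording.h5", confounds=study.confounds)
    np.save(OUT / "beta_true.npy", study.truth.beta_true)
    print(
        f"study: {study.table.n_frames} frames at {study.frame_rate} Hz, "
        f"{study.geometry.n_electrodes} electrodes over "
        f"{study.geometry.n_subjects} subjects; planted lag "
        f"{study.truth.lag_true * 1000:.0f} ms, "
        f"{int(study.truth.null_electrodes.sum())} null electrodes"
    )


if __name__ == "__main__":
    main()
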