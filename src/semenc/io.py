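"""Readers/writers for the pipeline's on-disk formats.

- embedding lexicon: word2vec text format (``<n> <dim>`` header, one
  ``label v1 ... vD`` line per label);
- frame labels: TSV with columns ``frame_idx  label  probability``;
- neural recording: HDF5 container with dataset ``hfb`` (electrodes x
  frames), group ``electrodes`` (subject, anat_label, x, y, z) and group
  ``stimulus`` (block, envelope);
- semantic components: scores/loadings TSV plus a JSON sidecar with the
  explained-variance ratios and the sign convention.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    ElectrodeGeometry,
    EmbeddingLexicon,
    FrameLabelTable,
    NeuralRecording,
    SemanticComponents,
    StimulusConfounds,
)

__all__ = [
    "write_lexicon",
    "read_lexicon",
    "write_label_table",
    "read_label_table",
    "write_recording",
    "read_recording",
    "write_components",
    "read_components",
]


def write_lexicon(lexicon: EmbeddingLexicon, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(lexicon.labels)} {lexicon.dim}\n")
        for lab, vec in zip(lexicon.labels, lexicon.vectors):
            fh.write(lab + " " + " ".join(f"{v:.6g}" for v in vec) + "\n")


def read_lexicon(path: str | Path) -> EmbeddingLexicon:
    with open(path) as fh:
        n, dim = map(int, fh.readline().split())
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : dim + 1]])
    if len(labels) != n:
        raise ValueError(f"header promised {n} labels, found {len(labels)}")
    return EmbeddingLexicon(labels=labels, vectors=np.array(rows))


def write_label_table(table: FrameLabelTable, path: str | Path) -> None:
    rows = [
        (f, lab, p)
        for f, entries in enumerate(table.labels_per_frame)
        for lab, p in entries
    ]
    df = pd.DataFrame(rows, columns=["frame_idx", "label", "probability"])
    df.to_csv(path, sep="\t", index=False)


def read_label_table(
    path: str | Path, n_frames: int | None = None, frame_rate: float = 25.0
) -> FrameLabelTable:
    df = pd.read_csv(path, sep="\t")
    if n_frames is None:
        n_frames = int(df["frame_idx"].max()) + 1 if len(df) else 0
    entries: list[list[tuple[str, float]]] = [[] for _ in range(n_frames)]
    for f, lab, p in df.itertuples(index=False):
        entries[int(f)].append((str(lab), float(p)))
    return FrameLabelTable(n_frames=n_frames, frame_rate=frame_rate, labels_per_frame=entries)


def write_recording(
    rec: NeuralRecording,
    path: str | Path,
    confounds: StimulusConfounds | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("hfb", data=rec.hfb)
        d.attrs["frame_rate"] = rec.frame_rate
        if rec.geometry is not None:
            g = fh.create_group("electrodes")
            g.create_dataset("subject", data=rec.geometry.subject_of)
            g.create_dataset("anat_label", data=np.array(rec.geometry.anat_label, dtype="S"))
            g.create_dataset("xyz", data=rec.geometry.sphere_xyz)
        if confounds is not None:
            s = fh.create_group("stimulus")
            s.create_dataset("block", data=confounds.block_design)
            s.create_dataset("envelope", data=confounds.audio_envelope)


def read_recording(path: str | Path) -> tuple[NeuralRecording, StimulusConfounds | None]:
    with h5py.File(path, "r") as fh:
        hfb = fh["hfb"][...]
        frame_rate = float(fh["hfb"].attrs["frame_rate"])
        geometry = None
        if "electrodes" in fh:
            g = fh["electrodes"]
            geometry = ElectrodeGeometry(
                subject_of=g["subject"][...],
                sphere_xyz=g["xyz"][...],
                anat_label=[b.decode() for b in g["anat_label"][...]],
            )
        confounds = None
        if "stimulus" in fh:
            s = fh["stimulus"]
            confounds = StimulusConfounds(
                block_design=s["block"][...], audio_envelope=s["envelope"][...]
            )
    return NeuralRecording(hfb=hfb, frame_rate=frame_rate, geometry=geometry), confounds


def write_components(components: SemanticComponents, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "scores.tsv", components.scores, delimiter="\t")
    np.savetxt(outdir / "loadings.tsv", components.loadings, delimiter="\t")
    np.savetxt(outdir / "mean.tsv", components.mean[None, :], delimiter="\t")
    meta = {
        "explained_variance_ratio": components.explained_variance_ratio.tolist(),
        "sign_convention": "largest-magnitude loading coefficient positive",
    }
    (outdir / "components.json").write_text(json.dumps(meta, indent=2))


def read_components(outdir: str | Path) -> SemanticComponents:
    outdir = Path(outdir)
    meta = json.loads((outdir / "components.json").read_text())
    return SemanticComponents(
        scores=np.loadtxt(outdir / "scores.tsv", delimiter="\t", ndmin=2),
        loadings=np.loadtxt(outdir / "loadings.tsv", delimiter="\t", ndmin=2),
        mean=np.loadtxt(outdir / "mean.tsv", delimiter="\t").ravel(),
        explained_variance_ratio=np.array(meta["explained_variance_ratio"]),
    )
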