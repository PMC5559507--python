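"""Readers and writers for the pipeline's on-disk formats.

EEG comes in either as EDF (read through MNE) or as the plain TSV matrix
dialect written by the simulator:

    rate<TAB><Hz>
    channels<TAB><label><TAB><label>...
    <one row per sample, one tab-separated column per channel, in µV>

Connectivity matrices are written as labelled CSV and as flat edge lists;
the ROI map is a two-column TSV (channel, roi); microstate models go to JSON
and label vectors to single-column TSV.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, ROIMap
from .microstates import LabelVector, MicrostateModel
from .preprocessing import EEGRecording


# -- EEG ---------------------------------------------------------------------

def write_eeg_tsv(rec: EEGRecording, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"rate\t{rec.rate!r}\n")
        fh.write("channels\t" + "\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")


def read_eeg_tsv(path: "str | Path") -> EEGRecording:
    path = Path(path)
    with path.open() as fh:
        header = {}
        for _ in range(2):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated header")
            key, _, rest = line.rstrip("\n").partition("\t")
            header[key] = rest
        for key in ("rate", "channels"):
            if key not in header:
                raise ValueError(f"{path}: missing header key {key!r}")
        rate = float(header["rate"])
        labels = header["channels"].split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {data.shape[1]} data columns for {len(labels)} channel labels"
        )
    return EEGRecording(data=data.T, rate=rate, labels=labels)


def read_eeg_edf(path: "str | Path") -> EEGRecording:
    """Read an EDF recording (via MNE); voltages converted to µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns Volts
    return EEGRecording(data=data, rate=float(raw.info["sfreq"]), labels=list(raw.ch_names))


def read_eeg(path: "str | Path") -> EEGRecording:
    """Dispatch on extension: .edf via MNE, .tsv/.txt via the matrix dialect."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return read_eeg_edf(path)
    if suffix in (".tsv", ".txt"):
        return read_eeg_tsv(path)
    raise ValueError(f"unknown EEG format {suffix!r} (expected .edf or .tsv)")


# -- connectivity ------------------------------------------------------------

def write_connectivity_csv(W: ConnectivityMatrix, path: "str | Path") -> None:
    pd.DataFrame(W.W, index=W.nodes, columns=W.nodes).to_csv(path)


def read_connectivity_csv(path: "str | Path") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(W=df.to_numpy(float), nodes=[str(c) for c in df.columns])


def write_edge_list(W: ConnectivityMatrix, path: "str | Path") -> None:
    rows = []
    n = W.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            rows.append((W.nodes[i], W.nodes[j], W.W[i, j]))
    pd.DataFrame(rows, columns=["node_i", "node_j", "value"]).to_csv(path, index=False)


# -- ROI map -----------------------------------------------------------------

def read_roi_map(path: "str | Path") -> ROIMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["channel", "roi"]:
        raise ValueError(f"{path}: expected columns ['channel', 'roi'], got {list(df.columns)}")
    if df["channel"].duplicated().any():
        dupes = df.loc[df["channel"].duplicated(), "channel"].tolist()
        raise ValueError(f"{path}: channels mapped more than once: {dupes}")
    return ROIMap(dict(zip(df["channel"], df["roi"])))


def write_roi_map(roi_map: ROIMap, path: "str | Path") -> None:
    pd.DataFrame(
        sorted(roi_map.mapping.items()), columns=["channel", "roi"]
    ).to_csv(path, sep="\t", index=False)


def default_roi_map() -> ROIMap:
    """The packaged 22-ROI map for the default 32-channel montage."""
    ref = resources.files("mspli.data").joinpath("roi_map_32.tsv")
    with resources.as_file(ref) as p:
        return read_roi_map(p)


# -- microstates -------------------------------------------------------------

def write_microstate_model(model: MicrostateModel, path: "str | Path") -> None:
    Path(path).write_text(
        json.dumps(
            {"k": model.k, "gev": model.gev, "templates": model.templates.tolist()}
        )
    )


def read_microstate_model(path: "str | Path") -> MicrostateModel:
    d = json.loads(Path(path).read_text())
    return MicrostateModel(templates=np.asarray(d["templates"]), k=d["k"], gev=d["gev"])


def write_labels(labels: LabelVector, path: "str | Path") -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# k\t{labels.k}\n")
        np.savetxt(fh, labels.labels, fmt="%d")


def read_labels(path: "str | Path") -> LabelVector:
    with Path(path).open() as fh:
        first = fh.readline()
        if not first.startswith("# k\t"):
            raise ValueError(f"{path}: missing '# k' header")
        k = int(first.split("\t")[1])
        values = np.loadtxt(fh, dtype=int, ndmin=1)
    return LabelVector(labels=values, k=k)


# -- cohort & misc -----------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: "str | Path") -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    return df


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
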