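"""End-to-end orchestration: filter -> phase -> microstates -> msPLI -> ROI ->
graph measures -> statistics, for every subject and band, with a manifest
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .connectivity import ROIMap, ms_pli, roi_aggregate
from .graphs import compute_graph_metrics
from .microstates import backfit, fit_microstates, select_k
from .preprocessing import DEFAULT_BANDS, POWER_BANDS, BandDefinition, EEGRecording, relative_band_power
from .stats import (
    DEFAULT_CONFOUNDS,
    correlate_edges,
    median_split_roc,
    residualize,
    sqrt_transform_aes,
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    eeg_dir: str = ""
    cohort_csv: str = ""
    roi_map: str = ""  # empty -> packaged default
    out_dir: str = "results"
    bands: list[list] = field(
        default_factory=lambda: [[b.name, b.low, b.high] for b in DEFAULT_BANDS]
    )
    k: int = 4
    k_range: "list[int] | None" = None  # set to select k by the KL criterion
    epoch_s: float = 4.0
    n_epochs: int = 4
    n_restarts: int = 10
    n_surrogates: int = 50
    n_perm: int = 10_000
    confounds: list[str] = field(default_factory=lambda: list(DEFAULT_CONFOUNDS))
    seed: int = 0
    roc_edge: str = "frontopolar_L--parietal_lateral_R"

    def band_definitions(self) -> list[BandDefinition]:
        return [BandDefinition(str(n), float(lo), float(hi)) for n, lo, hi in self.bands]

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: "str | Path") -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def subject_connectivity(
    rec: EEGRecording,
    config: RunConfig,
    roi_map: ROIMap,
    subject_seed: int,
) -> dict:
    """One subject's stage chain up to the ROI connectivity matrices."""
    if config.k_range is not None:
        k = select_k(rec, config.k_range, n_restarts=config.n_restarts, seed=subject_seed)
    else:
        k = config.k
    model = fit_microstates(rec, k=k, n_restarts=config.n_restarts, seed=subject_seed)
    labels = backfit(rec, model)
    epoch_len = int(round(config.epoch_s * rec.rate))
    out = {"k": k, "gev": model.gev, "bands": {}, "coverage": {}}
    for band in config.band_definitions():
        W_el = ms_pli(rec, labels, band, epoch_len=epoch_len, n_epochs=config.n_epochs)
        W_roi = roi_aggregate(W_el, roi_map)
        out["bands"][band.name] = W_roi
        out["coverage"][band.name] = W_el.coverage
    return out


def run_analysis(
    recordings: "list[EEGRecording]",
    cohort: pd.DataFrame,
    config: RunConfig,
    roi_map: "ROIMap | None" = None,
) -> dict:
    """The full in-memory analysis; returns a results bundle of DataFrames.

    Stages: per subject — microstate segmentation, msPLI per band, ROI
    aggregation, graph measures; cohort level — log transform + confound
    residualization, edge-wise Spearman against sqrt(AES) with max-statistic
    permutation correction per band, region-wise relative band power
    correlations, and the median-split ROC at the configured edge.
    """
    if len(recordings) != len(cohort):
        raise ValueError("one recording per cohort row required")
    roi_map = roi_map or mio.default_roi_map()
    bands = config.band_definitions()
    rng = np.random.default_rng([config.seed, 23])
    subject_seeds = rng.integers(0, 2**31 - 1, size=len(recordings))

    conn_rows = {b.name: [] for b in bands}
    graph_rows = []
    coverage_rows = []
    edge_names = None
    power_rows = []
    for s, rec in enumerate(recordings):
        res = subject_connectivity(rec, config, roi_map, int(subject_seeds[s]))
        for b in bands:
            W = res["bands"][b.name]
            if edge_names is None:
                edge_names = W.edge_names()
            conn_rows[b.name].append(W.edge_values())
            gm = compute_graph_metrics(
                W.W, n_surrogates=config.n_surrogates, seed=int(subject_seeds[s])
            )
            graph_rows.append({"subject": cohort["id"].iloc[s], "band": b.name, **gm.scalars()})
            coverage_rows.append(
                {
                    "subject": cohort["id"].iloc[s],
                    "band": b.name,
                    "n_matrices": sum(res["coverage"][b.name].values()),
                    **{f"ms{c}": v for c, v in res["coverage"][b.name].items()},
                }
            )
        power = relative_band_power(rec, POWER_BANDS, roi_map=roi_map.mapping)
        power_rows.append(power)

    connectivity = {
        b.name: pd.DataFrame(np.vstack(conn_rows[b.name]), columns=edge_names, index=cohort["id"])
        for b in bands
    }
    graph_metrics = pd.DataFrame(graph_rows)
    coverage = pd.DataFrame(coverage_rows)

    outcome = sqrt_transform_aes(cohort["AES"].to_numpy(float))
    confounds = cohort[list(config.confounds)]
    edge_stats = {}
    residuals = {}
    for b in bands:
        resid = residualize(connectivity[b.name].to_numpy(), confounds, log_transform=True)
        residuals[b.name] = resid
        edge_stats[b.name] = correlate_edges(
            resid, outcome, edge_names, n_perm=config.n_perm, seed=config.seed
        ).table.assign(band=b.name)

    # region-wise relative band power against AES, same statistical engine
    power_stack = pd.concat(power_rows, keys=cohort["id"])
    power_feats = power_stack.unstack(level=1)  # subjects x (band, roi)
    feat_names = [f"{band}:{roi}" for band, roi in power_feats.columns]
    power_resid = residualize(power_feats.to_numpy(float), confounds, log_transform=False)
    power_stats = correlate_edges(
        power_resid, outcome, feat_names, n_perm=config.n_perm, seed=config.seed
    ).table

    roc = None
    if config.roc_edge in (edge_names or []):
        band = "alpha2" if "alpha2" in connectivity else bands[0].name
        vals = connectivity[band][config.roc_edge].to_numpy(float)
        # the marker decreases with apathy, so score = -connectivity
        roc = median_split_roc(-vals, cohort["AES"].to_numpy(float))

    return {
        "connectivity": connectivity,
        "residuals": residuals,
        "graph_metrics": graph_metrics,
        "coverage": coverage,
        "edge_stats": pd.concat(edge_stats.values(), ignore_index=True),
        "band_power_stats": power_stats,
        "roc": roc,
        "edge_names": edge_names,
    }


def run_pipeline(config: RunConfig) -> dict:
    """File-based front end of :func:`run_analysis`.

    Reads the cohort CSV and one EEG file per subject id from ``eeg_dir``
    (``<id>.tsv`` or ``<id>.edf``), fails fast on missing inputs, executes
    the analysis and writes per-stage outputs plus a manifest (config hash,
    seeds, coverage) into ``out_dir``.
    """
    cohort = mio.read_cohort_csv(config.cohort_csv)
    eeg_dir = Path(config.eeg_dir)
    roi_map = mio.read_roi_map(config.roi_map) if config.roi_map else mio.default_roi_map()
    paths = []
    for sid in cohort["id"]:
        cands = [eeg_dir / f"{sid}.tsv", eeg_dir / f"{sid}.edf"]
        found = [p for p in cands if p.exists()]
        if not found:
            raise FileNotFoundError(f"no EEG file for subject {sid!r} in {eeg_dir}")
        paths.append(found[0])
    recordings = [mio.read_eeg(p) for p in paths]

    results = run_analysis(recordings, cohort, config, roi_map)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for band, df in results["connectivity"].items():
        df.to_csv(out / f"connectivity_{band}.csv")
    results["graph_metrics"].to_csv(out / "graph_metrics.csv", index=False)
    results["coverage"].to_csv(out / "coverage.csv", index=False)
    results["edge_stats"].to_csv(out / "edge_stats.csv", index=False)
    results["band_power_stats"].to_csv(out / "band_power_stats.csv", index=False)
    manifest = {
        "config": asdict(config),
        "config_hash": mio.config_hash(asdict(config)),
        "n_subjects": len(recordings),
        "inputs": [str(p) for p in paths],
    }
    if results["roc"] is not None:
        manifest["roc"] = {
            "auc": results["roc"].auc,
            "sensitivity": results["roc"].sensitivity,
            "specificity": results["roc"].specificity,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
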