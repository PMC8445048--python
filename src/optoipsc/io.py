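"""Session container I/O, run configuration, and end-to-end orchestration.

Sessions persist in an HDF5 layout (/sweeps, /truth, root attrs for
acquisition metadata and QC), event tables as CSV, and run configurations
as YAML. ``run_pipeline`` chains simulation, QC, two-pass detection, the
per-cell session analysis and the group statistics for one of the study's
scenario presets, processing one cell at a time so memory stays bounded.

Adapters for vendor acquisition formats (Axon Binary Format, Axograph) are
declared as an interface only; any reader that returns a ``Session`` can be
slotted into the pipeline in place of the simulator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import pipeline as pl
from . import stats as st
from .detect import DetectionConfig, EventTable, two_pass_detect
from .synth import (ConnectionParams, DrugProtocol, ParameterError,
                    Session, SessionConfig, SyntheticSession, TRUTH_COLUMNS,
                    simulate_vc_session)

log = logging.getLogger("optoipsc")

SCHEMA_VERSION = 1


class SessionFormatError(RuntimeError):
    """File is not a readable session container of a supported schema."""


# ---------------------------------------------------------------------------
# session container (HDF5 layout)
# ---------------------------------------------------------------------------

def write_session(session: Session, path: str | Path) -> None:
    """Persist a session: /sweeps dataset, /truth table, metadata in attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sample_rate"] = session.sample_rate
        f.attrs["sweep_len"] = session.sweep_len
        f.attrs["stim_time"] = session.stim_time
        f.attrs["polarity"] = session.polarity
        f.attrs["qc"] = json.dumps(
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in session.qc.items()})
        f.attrs["meta"] = json.dumps(session.meta, default=str)
        if session.sweeps is not None:
            f.create_dataset("sweeps", data=session.sweeps, dtype="f4")
        truth = getattr(session, "truth", None)
        if truth is not None and len(truth):
            grp = f.create_group("truth")
            for col in TRUTH_COLUMNS:
                data = truth[col].values
                if data.dtype == object:
                    data = data.astype("S16")
                grp.create_dataset(col, data=data)


def read_session(path: str | Path) -> Session:
    """Load a session container, validating the schema version.

    Unknown root attributes are preserved in ``session.meta`` so that files
    written by newer minor versions round-trip losslessly.
    """
    known = {"schema_version", "sample_rate", "sweep_len", "stim_time",
             "polarity", "qc", "meta"}
    try:
        with h5py.File(path, "r") as f:
            if "schema_version" not in f.attrs:
                raise SessionFormatError(f"{path}: not a session container")
            ver = int(f.attrs["schema_version"])
            if ver > SCHEMA_VERSION:
                raise SessionFormatError(f"{path}: unsupported schema version {ver}")
            meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
            for key in set(f.attrs) - known:
                meta[key] = f.attrs[key]
            qc = json.loads(f.attrs["qc"]) if "qc" in f.attrs else {}
            qc = {k: (np.asarray(v) if isinstance(v, list) else v)
                  for k, v in qc.items()}
            sweeps = f["sweeps"][...] if "sweeps" in f else None
            truth = None
            if "truth" in f:
                cols = {}
                for col in TRUTH_COLUMNS:
                    data = f["truth"][col][...]
                    if data.dtype.kind == "S":
                        data = data.astype(str)
                    cols[col] = data
                truth = pd.DataFrame(cols)
            kw = dict(sweeps=sweeps, sample_rate=float(f.attrs["sample_rate"]),
                      sweep_len=float(f.attrs["sweep_len"]),
                      stim_time=float(f.attrs["stim_time"]),
                      polarity=str(f.attrs["polarity"]), qc=qc, meta=meta)
    except OSError as exc:
        raise SessionFormatError(f"{path}: unreadable container ({exc})") from exc
    if truth is not None:
        return SyntheticSession(truth=truth, **kw)
    return Session(**kw)


# ---------------------------------------------------------------------------
# event-table CSV
# ---------------------------------------------------------------------------

def write_event_table(table: EventTable, path: str | Path) -> None:
    table.events.to_csv(path, index=False)


def read_event_table(path: str | Path) -> EventTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(EventTable.COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"{path}: missing columns {sorted(missing)}")
    return EventTable(df)


# ---------------------------------------------------------------------------
# vendor-format adapter interface (no implementation required)
# ---------------------------------------------------------------------------

def read_abf(path: str | Path) -> Session:  # pragma: no cover - adapter stub
    """Adapter hook for Axon Binary Format recordings (not implemented)."""
    raise NotImplementedError("ABF reading requires an external adapter")


def read_axograph(path: str | Path) -> Session:  # pragma: no cover - adapter stub
    """Adapter hook for Axograph recordings (not implemented)."""
    raise NotImplementedError("Axograph reading requires an external adapter")


# ---------------------------------------------------------------------------
# scenario presets and run configuration
# ---------------------------------------------------------------------------

SCENARIOS = ("agonist_d1_to_d2", "agonist_d2_to_d1", "antagonist_plus_agonist",
             "ttx", "no_drug", "fsi_source")

#: per-scenario defaults: (n_cells, DrugProtocol kwargs, ConnectionParams kwargs)
_SCENARIO_PRESETS: dict[str, tuple[int, dict, dict]] = {
    # D1->D2 connections recover more slowly than D2->D1 after washout
    "agonist_d1_to_d2": (12, dict(drug_kind="agonist", washout_tau=10.0), {}),
    "agonist_d2_to_d1": (6, dict(drug_kind="agonist", washout_tau=4.0), {}),
    "antagonist_plus_agonist": (5, dict(drug_kind="agonist_plus_antagonist"), {}),
    "ttx": (4, dict(drug_kind="ttx", onset_tau=1.25, washout_tau=15.0), {}),
    "no_drug": (6, dict(drug_kind="none"), {}),
    # FSI terminals lack the receptor: agonist applied but without effect
    "fsi_source": (4, dict(drug_kind="agonist", residual_release_fraction=1.0),
                   dict(n_connections=6, release_prob=0.8)),
}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, scenario presets included."""

    scenario: str = "agonist_d1_to_d2"
    n_cells: int | None = None
    seed: int = 0
    out_dir: str = "results"
    comparison_method: str = "holm_sidak"   # or "tukey"
    session: SessionConfig = field(default_factory=SessionConfig)
    connections: ConnectionParams = field(default_factory=ConnectionParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    qc: pl.QCCriteria = field(default_factory=pl.QCCriteria)
    windows: pl.PhaseWindows = field(default_factory=pl.PhaseWindows)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        preset_cells, proto_kw, conn_kw = _SCENARIO_PRESETS[self.scenario]
        if self.n_cells is None:
            self.n_cells = preset_cells
        self.protocol = DrugProtocol(**proto_kw)
        for k, v in conn_kw.items():
            setattr(self.connections, k, v)

    def config_hash(self) -> str:
        blob = json.dumps(to_dict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [to_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; nested sections mirror fields."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    kw = {}
    for key in ("scenario", "n_cells", "seed", "out_dir", "comparison_method"):
        if key in raw:
            kw[key] = raw[key]
    for key, cls in (("session", SessionConfig), ("connections", ConnectionParams),
                     ("detection", DetectionConfig), ("qc", pl.QCCriteria),
                     ("windows", pl.PhaseWindows)):
        if key in raw:
            section = dict(raw[key])
            for k, v in section.items():
                if isinstance(v, list):
                    section[k] = tuple(v)
            kw[key] = cls(**section)
    return RunConfig(**kw)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(to_dict(cfg), f, sort_keys=False)


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config: RunConfig
    summaries: pd.DataFrame          # cell x phase tidy table
    anova_amplitude: st.AnovaResult | None
    anova_success: st.AnovaResult | None
    comparisons: st.ComparisonSet | None
    qc_rejected: dict[str, list[str]]
    n_cells_analyzed: int


def analyze_session(session: Session, table: EventTable,
                    windows: pl.PhaseWindows, cell_id: str) -> pl.PhaseSummary:
    """Per-cell analysis: success-rate series, normalized amplitude, phases."""
    succ = pl.success_rate_per_minute(table, session)
    norm = pl.normalize_amplitude_series(table, session, windows)
    return pl.phase_summaries(norm, succ, windows, cell_id=cell_id)


def run_pipeline(cfg: RunConfig, write_outputs: bool = False) -> RunReport:
    """Simulate -> QC -> two-pass detect -> phase summaries -> group stats.

    Cells are simulated and analysed one at a time (seeds derived from
    ``cfg.seed``), QC rejections are logged with the rule that fired, and
    the group-level repeated-measures ANOVA plus the configured multiple
    comparison runs over the per-cell phase means.
    """
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_cells) % (2**31)
    summaries: list[pl.PhaseSummary] = []
    rejected: dict[str, list[str]] = {}
    for i, seed in enumerate(seeds):
        cell_id = f"cell{i:02d}"
        sess_cfg = dataclasses.replace(cfg.session, seed=int(seed))
        session = simulate_vc_session(sess_cfg, cfg.connections, cfg.protocol)
        verdict = pl.qc_cell(session, cfg.qc)
        if not verdict.passed:
            rejected[cell_id] = verdict.reasons
            for reason in verdict.reasons:
                log.info("QC reject %s: %s", cell_id, reason)
            continue
        table = two_pass_detect(session, cfg.detection)
        log.info("%s: %d pass-2 events (threshold %.1fx noise SD, floor %.0f pA)",
                 cell_id, len(table), cfg.detection.threshold_mult,
                 cfg.detection.min_amplitude)
        try:
            summaries.append(analyze_session(session, table, cfg.windows, cell_id))
        except pl.NormalizationError as exc:
            rejected[cell_id] = [f"analysis failed: {exc}"]
            log.info("reject %s: %s", cell_id, exc)

    tidy = pl.summaries_to_frame(summaries)
    anova_amp = anova_succ = comps = None
    if len(summaries) >= 2:
        amp = tidy.pivot(index="cell", columns="phase", values="norm_amplitude")
        amp = amp[["baseline", "drug", "washout"]]
        succ = tidy.pivot(index="cell", columns="phase", values="success_rate")
        succ = succ[["baseline", "drug", "washout"]]
        if not amp.isna().any().any():
            anova_amp = st.rm_anova_one_way(amp.values, gg=True)
            comps = st.pairwise_rm(amp.values, labels=list(amp.columns),
                                   method=cfg.comparison_method)
        if not succ.isna().any().any():
            anova_succ = st.rm_anova_one_way(succ.values, gg=True)

    report = RunReport(config=cfg, summaries=tidy, anova_amplitude=anova_amp,
                       anova_success=anova_succ, comparisons=comps,
                       qc_rejected=rejected, n_cells_analyzed=len(summaries))
    if write_outputs:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = cfg.config_hash()
        tidy.assign(config_hash=tag).to_csv(out / f"{cfg.scenario}_phases.csv",
                                            index=False)
        if anova_amp is not None:
            st.results_to_frame(anova_amp, comps).assign(config_hash=tag).to_csv(
                out / f"{cfg.scenario}_stats.csv", index=False)
    return report
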