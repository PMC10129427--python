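"""Configuration-driven orchestration of the full analysis.

``run_analyze`` takes a validated :class:`RunConfig` naming the subjects
(file path + group label) and runs preprocess -> epoching -> Welch power ->
per-band Pearson -> broadband Granger -> per-band PTE -> group contrasts
with ROC, writing every intermediate and final table to the output
directory together with a JSON manifest that fully reproduces the run.
``run_simulate`` writes a synthetic two-cohort dataset (plus ground truth)
that ``run_analyze`` can consume directly.

All tables are TSV with fixed float formatting, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, QeegError
from .signal_io import Recording, RegionMap, epoch_and_reject, preprocess, read_recording, write_recording
from .spectral_power import BandSet, cohort_power_table, summarize_power, welch_psd
from .connectivity import (
    ConnMatrix,
    PTEParams,
    granger_pairwise,
    interhemispheric_summary,
    pearson_connectivity,
    pte_connectivity,
    threshold_directed,
)
from .group_stats import ContrastResult, contrast_connectivity
from .synthetic_data import make_cohorts

__all__ = ["RunConfig", "CohortResults", "run_analyze", "run_simulate",
           "analyze_recordings", "save_conn_matrix", "load_conn_matrix"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated configuration shared by the analyze and simulate steps."""

    subjects: list[dict] = field(default_factory=list)
    notch_hz: float = 50.0
    band: tuple[float, float] = (0.5, 40.0)
    epoch_length_s: float = 2.0
    amplitude_limit_uv: float = 100.0
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    gc_max_order: int = 6
    gc_alpha: float = 0.05
    gc_edge_threshold: float = 0.01
    pte_delay: int | None = None
    pte_bins: int | None = None
    pooling: str = "per_edge_pooled"
    out_dir: str = "qeegconn_out"
    seed: int = 0
    # simulation-only keys
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        if cfg.pooling not in ("per_edge_pooled", "per_subject_mean"):
            raise ConfigError(f"unknown pooling {cfg.pooling!r}")
        return cfg

    def validate_subjects(self) -> None:
        if not self.subjects:
            raise ConfigError("no subjects in configuration")
        groups = set()
        ids = set()
        for s in self.subjects:
            missing = {"id", "path", "group"} - set(s)
            if missing:
                raise ConfigError(f"subject entry {s} missing keys {sorted(missing)}")
            if s["id"] in ids:
                raise ConfigError(f"duplicate subject id {s['id']!r}")
            ids.add(s["id"])
            groups.add(s["group"])
            if not Path(s["path"]).exists():
                raise ConfigError(f"subject {s['id']}: file not found: {s['path']}")
        if len(groups) != 2:
            raise ConfigError(
                f"contrast mode needs exactly two groups, got {sorted(groups)}"
            )


def save_conn_matrix(conn: ConnMatrix, path: Path) -> None:
    """TSV matrix (labels as header/index) + JSON sidecar with metadata."""
    df = pd.DataFrame(conn.values, index=conn.node_labels, columns=conn.node_labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="channel")
    meta = {"metric": conn.metric, "band": conn.band, "directed": conn.directed,
            "params": conn.params}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True, default=str))


def load_conn_matrix(path: Path) -> ConnMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ConnMatrix(values=df.values, metric=meta["metric"], band=meta["band"],
                      directed=meta["directed"], node_labels=list(df.columns),
                      params=meta.get("params", {}))


def _analyze_subject(rec: Recording, cfg: RunConfig, bands: BandSet):
    """Full single-subject chain: preprocess, epoch, power, connectivity."""
    rec = preprocess(rec, notch_hz=cfg.notch_hz, band=cfg.band)
    epochs = epoch_and_reject(rec, epoch_length_s=cfg.epoch_length_s,
                              amplitude_limit_uv=cfg.amplitude_limit_uv)
    spec = welch_psd(epochs, window_s=cfg.welch_window_s, overlap=cfg.welch_overlap)
    power = summarize_power(spec, bands=bands)
    conns: dict[tuple[str, str], ConnMatrix] = {}
    for name, band in bands:
        conns[("pearson", name)] = pearson_connectivity(epochs, band, band_name=name)
    gc, gc_bin = granger_pairwise(epochs, max_order=cfg.gc_max_order,
                                  alpha=cfg.gc_alpha)
    conns[("granger", "broadband")] = gc
    pte_params = PTEParams(delay=cfg.pte_delay, bins=cfg.pte_bins)
    for name, band in bands:
        conns[("pte", name)] = pte_connectivity(epochs, band, params=pte_params,
                                                band_name=name)
    n_kept = int(epochs.kept_mask.sum())
    return power, conns, gc_bin, {"epochs_kept": n_kept,
                                  "epochs_total": int(epochs.kept_mask.size)}


def _contrast_row(res: ContrastResult) -> dict:
    return {
        "metric": res.metric, "band": res.band,
        "U": res.test.u_statistic, "Z": res.test.z_value, "p": res.test.p_value,
        "AUC": res.roc.auc, "ci_low": res.roc.ci_low, "ci_high": res.roc.ci_high,
        "n1": res.test.n1, "n2": res.test.n2, "pooling": res.pooling,
        "group_a": res.group_names[0], "group_b": res.group_names[1],
        "mean_a": res.mean_a, "mean_b": res.mean_b,
    }


@dataclass
class CohortResults:
    """In-memory result bundle of a two-group cohort analysis."""

    groups: tuple[str, str]
    power: dict[str, list]                      # group -> PowerSummary list
    conn: dict[str, dict[tuple[str, str], list[ConnMatrix]]]
    contrasts: dict[tuple[str, str], ContrastResult]
    edge_summaries: dict[str, list[dict]]       # group -> per-subject GC edges

    def mean_dtabr(self, group: str) -> float:
        return float(np.mean([p.dtabr for p in self.power[group]]))

    def mean_band_ratio(self, group: str) -> dict[str, float]:
        bands = self.power[group][0].band_ratio.keys()
        return {b: float(np.mean([p.band_ratio[b] for p in self.power[group]]))
                for b in bands}

    def mean_region_ratio(self, group: str) -> dict[str, float]:
        regs = self.power[group][0].region_ratio.keys()
        return {r: float(np.mean([p.region_ratio[r] for p in self.power[group]]))
                for r in regs}


def analyze_recordings(
    recordings: dict[str, list[Recording]],
    config: RunConfig | dict | None = None,
) -> CohortResults:
    """Run the full analysis chain on in-memory recordings of two groups.

    The same chain as :func:`run_analyze` (preprocess, epoch, Welch power,
    per-band Pearson, broadband Granger, per-band PTE, contrasts, GC edge
    summaries) without touching disk.  Group A of each contrast is the
    alphabetically first group name.
    """
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    if len(recordings) != 2:
        raise ConfigError(f"need exactly two groups, got {sorted(recordings)}")
    bands = BandSet.default()
    regions = RegionMap.default()
    groups = tuple(sorted(recordings))
    power: dict[str, list] = {g: [] for g in groups}
    conn: dict[str, dict] = {g: {} for g in groups}
    edge_summaries: dict[str, list[dict]] = {g: [] for g in groups}
    for g in groups:
        for rec in recordings[g]:
            p, cmats, _gc_bin, _info = _analyze_subject(rec, config, bands)
            power[g].append(p)
            for key, cm in cmats.items():
                conn[g].setdefault(key, []).append(cm)
            edges = threshold_directed(cmats[("granger", "broadband")],
                                       config.gc_edge_threshold)
            hemi = interhemispheric_summary(edges, regions)
            edge_summaries[g].append({
                "n_edges": edges.n_edges,
                "total_intensity": edges.total_intensity,
                "cross_count": hemi["cross"]["count"],
                "cross_intensity": hemi["cross"]["intensity"],
            })
    contrasts = {}
    for key in conn[groups[0]]:
        contrasts[key] = contrast_connectivity(
            conn[groups[0]][key], conn[groups[1]][key],
            pooling=config.pooling, positive="A", group_names=groups,
        )
    return CohortResults(groups=groups, power=power, conn=conn,
                         contrasts=contrasts, edge_summaries=edge_summaries)


def run_analyze(config: RunConfig | dict | str, out_dir: str | None = None) -> Path:
    """Run the full analysis described by ``config``; returns the output dir.

    Subjects failing preprocessing are recorded in the manifest and
    excluded from contrasts; the run aborts only if a group ends up empty.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    if out_dir is not None:
        config.out_dir = str(out_dir)
    config.validate_subjects()

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bands = BandSet.default()
    regions = RegionMap.default()

    groups = sorted({s["group"] for s in config.subjects})
    per_group: dict[str, list[str]] = {g: [] for g in groups}
    powers: dict[str, object] = {}
    conns: dict[str, dict] = {}
    gc_bins: dict[str, ConnMatrix] = {}
    subject_status = {}
    for s in sorted(config.subjects, key=lambda s: s["id"]):
        sid = s["id"]
        try:
            rec = read_recording(s["path"], format=s.get("format"))
            power, conn, gc_bin, info = _analyze_subject(rec, config, bands)
        except QeegError as exc:
            subject_status[sid] = {"status": "failed", "error": str(exc),
                                   "group": s["group"]}
            continue
        subject_status[sid] = {"status": "ok", "group": s["group"], **info}
        per_group[s["group"]].append(sid)
        powers[sid] = power
        conns[sid] = conn
        gc_bins[sid] = gc_bin
        power.to_frame().to_csv(out / f"power_{sid}.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
        for (metric, band_name), cm in conn.items():
            save_conn_matrix(cm, out / f"conn_{metric}_{band_name}_{sid}.tsv")
    empty = [g for g in groups if not per_group[g]]
    if empty:
        raise QeegError(f"group(s) {empty} empty after exclusions; nothing to contrast")

    ok_ids = [sid for sid, st in subject_status.items() if st["status"] == "ok"]
    table = cohort_power_table(
        [powers[sid] for sid in ok_ids],
        [subject_status[sid]["group"] for sid in ok_ids],
    )
    table.to_csv(out / "cohort_power.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)

    ga, gb = groups
    contrast_rows = []
    contrast_keys = ([("pearson", b) for b in bands.names]
                     + [("granger", "broadband")]
                     + [("pte", b) for b in bands.names])
    for metric, band_name in contrast_keys:
        cohort_a = [conns[sid][(metric, band_name)] for sid in per_group[ga]]
        cohort_b = [conns[sid][(metric, band_name)] for sid in per_group[gb]]
        res = contrast_connectivity(cohort_a, cohort_b, pooling=config.pooling,
                                    positive="A", group_names=(ga, gb))
        contrast_rows.append(_contrast_row(res))
        roc_df = pd.DataFrame({"threshold": res.roc.thresholds,
                               "fpr": res.roc.fpr, "tpr": res.roc.tpr})
        roc_df.to_csv(out / f"roc_{metric}_{band_name}.tsv", sep="\t",
                      index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)

    edge_rows = []
    for sid in ok_ids:
        gc = conns[sid][("granger", "broadband")]
        edges = threshold_directed(gc, config.gc_edge_threshold)
        hemi = interhemispheric_summary(edges, regions)
        edge_rows.append({
            "subject": sid, "group": subject_status[sid]["group"],
            "n_edges": edges.n_edges, "total_intensity": edges.total_intensity,
            **{f"{cat}_{k}": v for cat, d in hemi.items() for k, v in d.items()},
        })
    pd.DataFrame(edge_rows).to_csv(out / "gc_edges.tsv", sep="\t", index=False,
                                   float_format=_FLOAT_FMT)

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in vars(config).items() if k != "subjects"},
        "subjects": subject_status,
        "groups": {g: sorted(per_group[g]) for g in groups},
        "gc_edge_threshold": config.gc_edge_threshold,
    }
    manifest["config"]["band"] = list(config.band)
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str)
    )
    return out


def run_simulate(config: RunConfig | dict | str, out_dir: str | None = None) -> Path:
    """Write a synthetic two-cohort dataset plus ground truth and a manifest.

    Simulation keys (``config.simulate``): ``n_cg`` (default 9), ``n_doc``
    (11), ``jitter`` (0.1), ``duration_s`` (profile default), ``format``
    ("matrix" or "edf").  The top-level ``seed`` drives everything.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    if out_dir is not None:
        config.out_dir = str(out_dir)
    sim = dict(config.simulate)
    unknown = set(sim) - {"n_cg", "n_doc", "jitter", "duration_s", "format"}
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    fmt = sim.get("format", "matrix")
    if fmt not in ("matrix", "edf"):
        raise ConfigError(f"unknown recording format {fmt!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cg, doc = make_cohorts(
        n_cg=int(sim.get("n_cg", 9)), n_doc=int(sim.get("n_doc", 11)),
        seed=config.seed, jitter=float(sim.get("jitter", 0.1)),
        duration_s=sim.get("duration_s"),
    )
    ext = "edf" if fmt == "edf" else "tsv"
    subjects = []
    for group, cohort in (("cg", cg), ("doc", doc)):
        for k, (rec, truth) in enumerate(cohort, start=1):
            sid = f"{group}{k:02d}"
            path = out / f"rec_{sid}.{ext}"
            write_recording(rec, path, format=fmt)
            (out / f"truth_{sid}.json").write_text(truth.to_json())
            subjects.append({"id": sid, "path": str(path), "group": group,
                             "format": fmt})
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "simulate": {**sim, "format": fmt},
        "subjects": subjects,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str)
    )
    # ready-to-run analyze configuration pointing at the written files
    (out / "analyze.yaml").write_text(
        yaml.safe_dump({"subjects": subjects, "seed": config.seed,
                        "out_dir": str(out / "analysis")}, sort_keys=True)
    )
    return out
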