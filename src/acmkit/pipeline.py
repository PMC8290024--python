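"""End-to-end orchestration: simulate or ingest, preprocess, TAP, summarize,
group tables and waveforms, screening.

`run_pipeline` is deterministic given its configuration (all randomness is
seeded from config fields) and every output file records the config hash,
so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as acm_io
from . import metrics, synthetic, tap
from .screening import compare_variables, split_protocol
from .series import RegularSeries

logger = logging.getLogger(__name__)

CHANNELS = ("wt", "activity", "position", "tap")

#: screening candidates mirroring the published shortlist
DEFAULT_CANDIDATES = ("wt_IS", "wt_CFI", "tap_CFI", "activity_L5")


@dataclass
class GroupSpecConfig:
    label: str
    n: int
    ahi: float | None = None
    cpap_factor: float | None = None

    def phenotype(self) -> synthetic.PhenotypeSpec:
        kw = {}
        if self.ahi is not None:
            kw["ahi"] = self.ahi
        if self.cpap_factor is not None:
            kw["cpap_factor"] = self.cpap_factor
        return synthetic.phenotype(self.label, **kw)


@dataclass
class ScreeningConfig:
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    contrast: tuple[str, str] = ("healthy", "severe")  # (negative, positive) group labels
    positive_group: str | None = None
    n_iter: int = 100
    train_frac: float = 0.66
    seed: int = 0


@dataclass
class PipelineConfig:
    """Configuration of one analysis run (YAML/JSON-serializable)."""

    mode: str = "simulate"  # simulate | ingest
    groups: tuple[GroupSpecConfig, ...] = (
        GroupSpecConfig("healthy", 3),
        GroupSpecConfig("severe", 3),
    )
    days: int = 7
    seed: int = 0
    data_dir: str | None = None  # ingest mode: directory with device CSVs + manifest
    outdir: str = "acm_run"
    bin_minutes: int = 10
    np_bin_minutes: int | None = None
    min_days: int = 6
    wt_range: tuple[float, float] = acm_io.WT_RANGE
    wt_spike_delta: float = acm_io.WT_SPIKE_DELTA
    lo_pct: float = tap.DEFAULT_PCT[0]
    hi_pct: float = tap.DEFAULT_PCT[1]
    tap_missing: str = "mask"
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(GroupSpecConfig(**g) for g in d["groups"])
        if "screening" in d and isinstance(d["screening"], dict):
            sc = dict(d["screening"])
            if "candidates" in sc:
                sc["candidates"] = tuple(sc["candidates"])
            if "contrast" in sc:
                sc["contrast"] = tuple(sc["contrast"])
            d["screening"] = ScreeningConfig(**sc)
        for key in ("wt_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject_id!r}: {cause}")
        self.stage = stage
        self.subject_id = subject_id


def process_recording(rec: acm_io.AcmRecording, config: PipelineConfig) -> dict[str, RegularSeries]:
    """Preprocess one recording into the four aligned analysis channels."""
    channels = acm_io.regularize_recording(
        rec,
        bin_minutes=config.bin_minutes,
        wt_range=config.wt_range,
        spike_delta=config.wt_spike_delta,
    )
    wt_n = tap.normalize_channel(channels["wt"], invert=True, lo_pct=config.lo_pct, hi_pct=config.hi_pct)
    act_n = tap.normalize_channel(channels["activity"], lo_pct=config.lo_pct, hi_pct=config.hi_pct)
    pos_n = tap.normalize_channel(channels["position"], lo_pct=config.lo_pct, hi_pct=config.hi_pct)
    channels["tap"] = tap.integrate_tap(wt_n, act_n, pos_n, missing=config.tap_missing)
    return channels


def summarize_subject(
    rec: acm_io.AcmRecording, config: PipelineConfig
) -> tuple[list[dict], dict[str, RegularSeries]]:
    """Rows of the tidy summary table (one per channel) for one subject."""
    try:
        channels = process_recording(rec, config)
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise StageError("preprocess", rec.subject_id, exc) from exc
    rows = []
    for name in CHANNELS:
        try:
            summ = metrics.summarize(
                channels[name], min_days=config.min_days, np_bin_minutes=config.np_bin_minutes
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"summarize:{name}", rec.subject_id, exc) from exc
        row = {"subject_id": rec.subject_id, "group": rec.metadata.get("group", ""), "channel": name}
        row.update(summ.as_dict())
        rows.append(row)
    return rows, channels


def load_cohort(config: PipelineConfig) -> tuple[list[acm_io.AcmRecording], pd.DataFrame]:
    """Obtain the cohort per config: simulate it, or ingest device CSVs."""
    if config.mode == "simulate":
        cohort = synthetic.CohortSpec(
            groups=tuple((g.phenotype(), g.n) for g in config.groups),
            days=config.days,
            seed=config.seed,
        )
        return synthetic.generate_cohort(cohort)
    if config.mode == "ingest":
        if not config.data_dir:
            raise ValueError("ingest mode requires data_dir")
        manifest = pd.read_csv(os.path.join(config.data_dir, "manifest.csv"))
        recordings = []
        for row in manifest.itertuples():
            wt = acm_io.read_wt_log(os.path.join(config.data_dir, f"{row.subject_id}_wt.csv"))
            tilt = acm_io.read_tilt_log(os.path.join(config.data_dir, f"{row.subject_id}_tilt.csv"))
            meta = {k: getattr(row, k) for k in ("group", "age", "sex", "bmi") if hasattr(row, k)}
            recordings.append(
                acm_io.AcmRecording(subject_id=str(row.subject_id), wt_raw=wt, tilt_raw=tilt, metadata=meta)
            )
        return recordings, manifest
    raise ValueError(f"unknown mode {config.mode!r}")


def group_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of every numeric circadian parameter per group x channel."""
    numeric = ["IS", "IV", "RA", "CFI", "M10", "L5"]
    rows = []
    for (group, channel), sub in summaries.groupby(["group", "channel"], sort=True):
        row = {"group": group, "channel": channel, "n": len(sub)}
        for col in numeric:
            x = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = x.mean()
            row[f"{col}_sem"] = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def group_waveforms(
    per_subject: dict[str, dict[str, RegularSeries]],
    grouping: dict[str, str],
) -> pd.DataFrame:
    """Across-subject mean +/- SEM of individual daily waveforms per group.

    Individual mean waveforms are computed first and then averaged per
    group, bin by bin.  Singleton groups get a flagged NaN SEM.
    """
    rows = []
    groups: dict[str, list[str]] = {}
    for sid, grp in grouping.items():
        groups.setdefault(grp, []).append(sid)
    for grp, sids in sorted(groups.items()):
        for channel in CHANNELS:
            wfs = []
            for sid in sids:
                if channel in per_subject[sid]:
                    wf = metrics.mean_waveform(per_subject[sid][channel])
                    wfs.append(np.where(wf.mask, wf.values, np.nan))
            if not wfs:
                continue
            arr = np.vstack(wfs)
            mean = np.nanmean(arr, axis=0)
            if arr.shape[0] > 1:
                sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(arr), axis=0))
            else:
                sem = np.full(arr.shape[1], np.nan)
            for b in range(mean.size):
                minutes = b * per_subject[sids[0]][channel].bin_minutes
                rows.append(
                    {
                        "group": grp,
                        "channel": channel,
                        "time_of_day": f"{minutes // 60:02d}:{minutes % 60:02d}",
                        "mean": mean[b],
                        "sem": sem[b],
                        "n_subjects": arr.shape[0],
                    }
                )
    return pd.DataFrame(rows)


def _variable_column(summaries: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Wide view of one `channel_PARAM` screening variable per subject."""
    channel, param = variable.rsplit("_", 1)
    sub = summaries[summaries["channel"] == channel]
    if sub.empty or param not in sub.columns:
        raise ValueError(f"unknown screening variable {variable!r}")
    return sub[["subject_id", "group", param]].rename(columns={param: "value"})


def run_screening(summaries: pd.DataFrame, sconf: ScreeningConfig) -> dict:
    """Fit and evaluate the decision stump for every candidate variable.

    Candidates are compared pairwise by a Wilcoxon signed-rank test on
    their per-iteration test AUC across the shared split seeds.
    """
    neg_group, pos_group = sconf.contrast
    positive = sconf.positive_group or pos_group
    results: dict = {"contrast": list(sconf.contrast), "positive_class": positive,
                     "seed": sconf.seed, "n_iter": sconf.n_iter,
                     "train_frac": sconf.train_frac, "candidates": {}}
    protocols = {}
    for variable in sconf.candidates:
        col = _variable_column(summaries, variable)
        col = col[col["group"].isin(sconf.contrast)]
        values = col["value"].to_numpy(dtype=float)
        labels = col["group"].to_numpy()
        proto = split_protocol(
            values,
            labels,
            n_iter=sconf.n_iter,
            train_frac=sconf.train_frac,
            seed=sconf.seed,
            variable=variable,
            positive_class=positive,
        )
        protocols[variable] = proto
        results["candidates"][variable] = {
            "best_rule": proto.best_rule.as_dict(),
            "refit_rule": proto.refit_rule.as_dict(),
            "best_iteration": proto.best_iteration,
            "best_test_report": proto.best_report.as_dict(),
            "mean_test_agreement": float(np.nanmean(proto.test_agreements)),
            "mean_test_auc": float(np.nanmean(proto.test_aucs)),
        }
    names = list(protocols)
    results["wilcoxon_test_auc"] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            cmp_ = compare_variables(protocols[a].test_aucs, protocols[b].test_aucs)
            results["wilcoxon_test_auc"][f"{a}_vs_{b}"] = {
                "p_value": cmp_.p_value,
                "degenerate": cmp_.degenerate,
            }
    return results


@dataclass
class PipelineResult:
    outdir: str
    config_hash: str
    summaries: pd.DataFrame
    group_table: pd.DataFrame
    waveforms: pd.DataFrame
    screening: dict
    paths: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the artifact bundle to ``config.outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    chash = config.config_hash()
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("acmkit")
    root.addHandler(handler)
    try:
        logger.info("config hash %s", chash)
        recordings, manifest = load_cohort(config)
        all_rows: list[dict] = []
        per_subject: dict[str, dict[str, RegularSeries]] = {}
        grouping: dict[str, str] = {}
        for rec in recordings:
            rows, channels = summarize_subject(rec, config)
            all_rows.extend(rows)
            per_subject[rec.subject_id] = channels
            grouping[rec.subject_id] = rec.metadata.get("group", "")
        summaries = pd.DataFrame(all_rows)
        gtable = group_table(summaries)
        waveforms = group_waveforms(per_subject, grouping)
        screening = run_screening(summaries, config.screening)
    finally:
        root.removeHandler(handler)
        handler.close()

    paths = {
        "manifest": os.path.join(config.outdir, "manifest.csv"),
        "summaries": os.path.join(config.outdir, "summaries.csv"),
        "group_table": os.path.join(config.outdir, "group_table.csv"),
        "waveforms": os.path.join(config.outdir, "waveforms.csv"),
        "screening": os.path.join(config.outdir, "screening.json"),
        "log": log_path,
    }
    header = f"# acmkit config_hash={chash}\n"
    manifest.to_csv(paths["manifest"], index=False)
    for key, df in (("summaries", summaries), ("group_table", gtable), ("waveforms", waveforms)):
        with open(paths[key], "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6g")
    screening_out = {"config_hash": chash, **screening}
    with open(paths["screening"], "w") as fh:
        json.dump(screening_out, fh, indent=2, default=str)
    return PipelineResult(
        outdir=config.outdir,
        config_hash=chash,
        summaries=summaries,
        group_table=gtable,
        waveforms=waveforms,
        screening=screening_out,
        paths=paths,
    )
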