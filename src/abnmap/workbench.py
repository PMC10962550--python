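"""End-to-end orchestration: simulate -> (preprocess -> bandpower) ->
normative -> localization -> temporal -> report.

A run is configured by a :class:`RunConfig` (YAML-loadable), writes all
tabular artefacts plus a text report into its output directory, and
records a manifest carrying the run id, the SHA-256 hash of the resolved
configuration, and per-file checksums, so any run can be audited and
reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import localization, normative, temporal
from .bandpower import windowed_band_features
from .localization import PatientSummary
from .preprocess import preprocess_recording
from .synthetic import SyntheticSpec, generate_normative_cohort, generate_surgical_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "abnmap_run"
    seed: int = 0
    entry: str = "features"  # "features" (synthetic band powers) or "signals"
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    line_hz: float = 50.0
    min_subjects: int = 5
    periictal_horizon_s: float = 3600.0
    circadian_tolerance_rad: float = float(np.pi / 4)
    relative_mode: str = "log_then_normalize"
    k_grid: tuple[int, ...] = (1, 5, 30)
    subsample_reps: int = 100
    run_subsampling: bool = False
    # signal-entry knobs
    n_signal_patients: int = 6
    signal_fs: float = 200.0
    signal_regions: int = 10
    channels_per_region: int = 2

    def validate(self) -> None:
        if self.entry not in ("features", "signals"):
            raise ValueError("entry must be 'features' or 'signals'")
        if self.relative_mode not in ("log_then_normalize", "normalize_then_log"):
            raise ValueError("unknown relative_mode")
        if self.min_subjects < 1 or self.subsample_reps < 1:
            raise ValueError("counts must be >= 1")
        if self.line_hz not in (50.0, 60.0):
            raise ValueError("line_hz must be 50 or 60")
        if self.periictal_horizon_s <= 0 or self.circadian_tolerance_rad <= 0:
            raise ValueError("horizons/tolerances must be positive")
        if any(k < 1 for k in self.k_grid):
            raise ValueError("k grid entries must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.k_grid, list):
            cfg.k_grid = tuple(int(k) for k in cfg.k_grid)
        for key in ("n_regions_covered_range", "n_resected_range"):
            if key in cfg.synthetic and isinstance(cfg.synthetic[key], list):
                cfg.synthetic[key] = tuple(cfg.synthetic[key])
        cfg.validate()
        return cfg

    def spec(self) -> SyntheticSpec:
        return SyntheticSpec(seed=self.seed, **self.synthetic)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    normative_map: normative.NormativeMap
    summaries: list[PatientSummary]
    evaluation: localization.OutcomeEvaluation
    evaluation_interictal: localization.OutcomeEvaluation | None
    evaluation_periictal: localization.OutcomeEvaluation | None
    drs_series: dict[str, localization.DrsSeries]
    subsampling: pd.DataFrame | None


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir")  # where a run lands does not change what it computes
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _write_manifest(out: Path, run_id: str, cfg_hash: str) -> None:
    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps({"run_id": run_id, "config_sha256": cfg_hash, "files": files}, indent=1)
    )


def _patient_stage(cfg: RunConfig, nmap: normative.NormativeMap, patients):
    """Score, label, and summarise every patient; returns summaries + series + tables."""
    summaries, series_by_patient, label_rows, drs_rows = [], {}, [], []
    for pat in patients:
        abnorm = normative.score_patient(pat.bandpower, nmap)
        resected = {r: pat.resected[r] for r in abnorm.region_ids}
        if not any(resected.values()) or all(resected.values()):
            logger.warning("patient %s unevaluable: one-class coverage", pat.patient_id)
            continue
        series = localization.drs_timeseries(abnorm, resected)
        from .preprocess import WindowGrid

        grid = WindowGrid(
            window_starts=pat.bandpower.window_starts, valid=pat.bandpower.valid
        )
        seiz_labels = temporal.label_seizure_proximity(
            grid, pat.seizures, horizon_s=cfg.periictal_horizon_s
        )
        circ_labels = circ_phase = None
        try:
            ratio = temporal.alpha_delta_ratio(pat.bandpower)
            circ_phase = temporal.circadian_phase(ratio)
            circ_labels = temporal.label_circadian(circ_phase, cfg.circadian_tolerance_rad)
        except ValueError as e:
            logger.info("patient %s: circadian labels unavailable (%s)", pat.patient_id, e)
        labels = temporal.window_label_frame(grid, seiz_labels, circ_labels, circ_phase)
        summary = localization.summarize_patient(
            series, labels, patient_id=pat.patient_id, ilae_class=pat.truth.ilae_class
        )
        summaries.append(summary)
        series_by_patient[pat.patient_id] = series
        lab = labels.copy()
        lab.insert(0, "patient_id", pat.patient_id)
        label_rows.append(lab)
        drs_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pat.patient_id,
                    "window_start_s": series.window_starts,
                    "drs": series.values,
                }
            )
        )
    return summaries, series_by_patient, label_rows, drs_rows


def _summary_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "patient_id": s.patient_id,
                "ilae_class": s.ilae_class,
                "n_windows": s.n_windows,
                "median_drs": s.median_drs,
                "localizing_pct": s.localizing_pct,
                **{f"median_drs_{k.replace('-', '_')}": v for k, v in s.condition_medians.items()},
            }
        )
    return pd.DataFrame(rows)


def _ascii_hist(values: np.ndarray, width: int = 40) -> list[str]:
    counts, edges = np.histogram(values, bins=10, range=(0.0, 1.0))
    peak = max(counts.max(), 1)
    return [
        f"  {edges[i]:.1f}-{edges[i + 1]:.1f} | {'#' * int(round(width * c / peak))} {c}"
        for i, c in enumerate(counts)
    ]


def _report(cfg, result_rows, summaries, ev, ev_int, ev_peri, series_by_patient) -> str:
    lines = ["abnmap pipeline report", "=" * 40, ""]
    lines += result_rows
    lines.append("")
    lines.append(f"patients evaluated: {len(summaries)}")
    lines.append(
        f"outcome AUC (median D_RS, ILAE>1 positive): {ev.auc:.3f} "
        f"(one-sided rank-sum p={ev.ranksum_p:.4f}; n={ev.n_good} good / {ev.n_poor} poor)"
    )
    if ev_int is not None:
        lines.append(f"outcome AUC, interictal medians: {ev_int.auc:.3f}")
    if ev_peri is not None:
        lines.append(f"outcome AUC, peri-ictal medians: {ev_peri.auc:.3f}")
    lines.append("")
    for s in summaries:
        lines.append(
            f"{s.patient_id} (ILAE {s.ilae_class}): median D_RS {s.median_drs:.3f}, "
            f"localizing {s.localizing_pct:.1f}% over {s.n_windows} windows"
        )
        lines.extend(_ascii_hist(series_by_patient[s.patient_id].values))
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a full synthetic-cohort study and write all artefacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    run_id = f"run_{cfg_hash[:12]}"
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    spec = config.spec()
    cohort, coverage = generate_normative_cohort(spec)
    cohort.to_csv(out / "normative_cohort.csv", index=False)
    nmap = normative.build_normative_map(
        cohort, min_subjects=config.min_subjects, cohort_id=run_id
    )
    nmap.to_csv(out / "normative_map.csv")
    nmap.to_json(out / "normative_map.json")
    stage_rows = [
        f"normative cohort: {spec.n_normative_subjects} subjects, "
        f"{coverage.size} regions covered, {len(nmap.region_ids)} retained (>= {config.min_subjects} subjects)"
    ]

    if config.entry == "signals":
        patients = _signal_entry(config, spec, out, stage_rows)
    else:
        patients = generate_surgical_cohort(spec)
    outcomes = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "ilae_class": [p.truth.ilae_class for p in patients],
        }
    )
    outcomes.to_csv(out / "outcomes.csv", index=False)
    pd.concat([p.seizures.to_frame(p.patient_id) for p in patients], ignore_index=True).to_csv(
        out / "seizures.csv", index=False
    )
    for p in patients:
        p.truth.to_json(out / f"ground_truth_{p.patient_id}.json")

    summaries, series_by_patient, label_rows, drs_rows = _patient_stage(config, nmap, patients)
    if not summaries:
        raise ValueError("no evaluable patient; pipeline halted after localization stage")
    stage_rows.append(
        f"patients: {len(patients)} simulated, {len(summaries)} evaluable "
        f"({len(patients) - len(summaries)} dropped)"
    )
    pd.concat(drs_rows, ignore_index=True).to_csv(out / "drs_windows.csv", index=False)
    pd.concat(label_rows, ignore_index=True).to_csv(out / "window_labels.csv", index=False)
    _summary_frame(summaries).to_csv(out / "patient_summaries.csv", index=False)

    ev = localization.evaluate_outcomes(summaries, "overall")
    ev.roc_points.to_csv(out / "roc_points.csv", index=False)

    def _try_eval(stat: str):
        try:
            return localization.evaluate_outcomes(summaries, stat)
        except (ValueError, KeyError):
            return None

    ev_int = _try_eval("interictal")
    ev_peri = _try_eval("peri-ictal")
    (out / "outcome_evaluation.json").write_text(
        json.dumps(
            {
                "auc": ev.auc,
                "ranksum_p": ev.ranksum_p,
                "signed_rank_p_poor": ev.signed_rank_p_poor,
                "signed_rank_p_good": ev.signed_rank_p_good,
                "auc_interictal": None if ev_int is None else ev_int.auc,
                "auc_periictal": None if ev_peri is None else ev_peri.auc,
                "n_good": ev.n_good,
                "n_poor": ev.n_poor,
            },
            indent=1,
        )
    )

    subsampling = None
    if config.run_subsampling:
        subsampling = temporal.run_subsampling_experiment(
            series_by_patient,
            {s.patient_id: s.ilae_class for s in summaries},
            k_grid=tuple(k for k in config.k_grid if k <= min(len(s) for s in series_by_patient.values())),
            n_reps=config.subsample_reps,
            seed=config.seed,
        )
        subsampling.to_csv(out / "subsampling_auc.csv", index=False)

    (out / "report.txt").write_text(
        _report(config, stage_rows, summaries, ev, ev_int, ev_peri, series_by_patient)
    )
    _write_manifest(out, run_id, cfg_hash)
    return PipelineResult(
        out_dir=out,
        normative_map=nmap,
        summaries=summaries,
        evaluation=ev,
        evaluation_interictal=ev_int,
        evaluation_periictal=ev_peri,
        drs_series=series_by_patient,
        subsampling=subsampling,
    )


def _signal_entry(config: RunConfig, spec: SyntheticSpec, out: Path, stage_rows: list[str]):
    """Signal-level entry: synthesize voltages, run the spectral chain."""
    from .io import write_recording
    from .synthetic import PatientFeatures, generate_patient_signal
    from .preprocess import WindowGrid
    from .temporal import SeizureTable

    patients = []
    n_good = (config.n_signal_patients + 1) // 2
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for j in range(config.n_signal_patients):
        outcome = "good" if j < n_good else "poor"
        rec, meta, truth = generate_patient_signal(
            spec,
            outcome,
            seed=j,
            fs=config.signal_fs,
            n_signal_regions=config.signal_regions,
            channels_per_region=config.channels_per_region,
            line_hz=config.line_hz,
            patient_id=f"patient_sig_{j:03d}",
        )
        write_recording(rec, rec_dir / truth.patient_id)
        meta.to_csv(rec_dir / f"{truth.patient_id}_channels.csv", index=False)
        clean, grid, bad = preprocess_recording(rec, line_hz=config.line_hz)
        meta = meta.copy()
        meta.loc[meta["channel_id"].isin(bad), "bad"] = 1
        bp = windowed_band_features(
            clean.data, clean.fs, grid, clean.channel_ids, meta, mode=config.relative_mode
        )
        region_res = localization.label_resected_regions(meta)
        resected = {r: bool(region_res.get(r, False)) for r in bp.region_ids}
        patients.append(
            PatientFeatures(
                patient_id=truth.patient_id,
                bandpower=bp,
                resected=resected,
                seizures=SeizureTable(
                    np.array(truth.seizure_onsets_s), np.array(truth.seizure_offsets_s)
                )
                if truth.seizure_onsets_s
                else SeizureTable(np.array([]), np.array([])),
                truth=truth,
            )
        )
        stage_rows.append(
            f"{truth.patient_id}: {len(rec.channel_ids)} channels, {len(bad)} flagged bad, "
            f"{int(grid.valid.sum())}/{grid.n_windows} valid windows"
        )
    return patients
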