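"""End-to-end pipeline: filter -> polarity -> fiducials -> anomaly.

``PipelineConfig`` collects every stage's parameters (validated up front so
a bad configuration aborts before any artifact is written) and
``run_pipeline`` executes the stages in order, writing the filtered signal,
a cluster/polarity report, the fiducial table, the anomaly-labeled table, a
manifest recording the configuration and seeds, and a per-stage log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .anomaly import AnomalyModelSpec, fit_predict_anomalies
from .fiducials import FiducialWindows, detect_fiducials, detect_r_peaks
from .io import read_signal, write_fiducial_table, write_signal
from .polarity import cluster_amplitudes, assess_polarity, correct_polarity
from .preprocessing import FilterSpec, MedianSpec, suppress_noise
from .signal import ECGSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for one pipeline run. Unknown keys are rejected."""

    input: str = ""
    output_dir: str = "ecgflow_out"
    fs: float = 360.0
    f_lo: float = 0.5
    f_hi: float = 100.0
    filter_order: int = 2
    median_window: int = 3
    mains: float | None = 50.0
    cluster_k: int = 5
    seed: int = 0
    min_rr: float = 0.2
    threshold_factor: float = 0.5
    heart_rate_hint: float | None = None
    anomaly_features: str = "raw"

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(f_lo=self.f_lo, f_hi=self.f_hi, order=self.filter_order, fs=self.fs)

    def median_spec(self) -> MedianSpec:
        return MedianSpec(window=self.median_window)

    def windows(self) -> FiducialWindows:
        if self.heart_rate_hint is not None:
            return FiducialWindows.for_heart_rate(self.heart_rate_hint, fs=self.fs)
        return FiducialWindows(fs=self.fs)

    def anomaly_spec(self) -> AnomalyModelSpec:
        return AnomalyModelSpec(features=self.anomaly_features)

    def validate(self) -> None:
        """Instantiate every sub-spec so invalid values fail fast."""
        self.filter_spec()
        self.median_spec()
        self.windows()
        self.anomaly_spec()
        if self.mains is not None and not 0 < self.mains < self.fs / 2:
            raise ValueError(f"mains {self.mains} Hz outside (0, fs/2)")
        if self.cluster_k < 2:
            raise ValueError("cluster_k must be >= 2")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)


def run_pipeline(config: PipelineConfig, signal: ECGSignal | None = None) -> dict:
    """Run every stage and write the artifacts; returns artifact paths.

    ``signal`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is read from ``config.input``. The configuration is
    validated before any output is produced, and the first failing stage
    aborts the run with its name in the raised error.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    artifacts = {"log": str(log_path)}
    timings = {}
    try:
        if signal is None:
            signal = _stage("read", lambda: read_signal(config.input, fs=config.fs), timings)

        filtered = _stage(
            "filter",
            lambda: suppress_noise(
                signal, config.filter_spec(), config.median_spec(), config.mains
            ),
            timings,
        )
        path = out_dir / "filtered_signal.csv"
        write_signal(path, filtered)
        artifacts["filtered_signal"] = str(path)

        def _polarity():
            model = cluster_amplitudes(filtered, k=config.cluster_k, seed=config.seed)
            verdict = assess_polarity(filtered, model)
            return correct_polarity(filtered, verdict), model, verdict

        oriented, model, verdict = _stage("polarity", _polarity, timings)
        path = out_dir / "cluster_report.json"
        path.write_text(
            json.dumps(
                {
                    "k": model.k,
                    "clusters": [
                        {"centroid": c, "size": s} for c, s in model.sorted_report()
                    ],
                    "polarity": verdict.verdict.value,
                    "evidence_ratio": verdict.evidence_ratio,
                },
                indent=2,
            )
        )
        artifacts["cluster_report"] = str(path)

        def _fiducials():
            r = detect_r_peaks(
                oriented, min_rr=config.min_rr, threshold_factor=config.threshold_factor
            )
            table = detect_fiducials(oriented, r, config.windows())
            logger.info("fiducials: %d R peaks, %d beats retained", len(r), len(table))
            return table

        table = _stage("fiducials", _fiducials, timings)
        path = out_dir / "fiducials.csv"
        write_fiducial_table(path, table)
        artifacts["fiducials"] = str(path)

        labeled = _stage(
            "anomaly", lambda: fit_predict_anomalies(table, config.anomaly_spec()), timings
        )
        path = out_dir / "anomalies.csv"
        write_fiducial_table(path, labeled)
        artifacts["anomalies"] = str(path)

        manifest = {
            "ecgflow_version": __version__,
            "config": dataclasses.asdict(config),
            "seeds": {"cluster": config.seed, "isolation_forest": config.anomaly_spec().random_state},
            "stage_seconds": timings,
            "beats": len(table),
            "anomalous_beats": int((labeled["Anomaly"] == -1).sum()),
            "polarity": verdict.verdict.value,
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = str(path)
        return artifacts
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name: str, fn, timings: dict):
    start = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - start, 4)
    logger.info("stage %s done in %.3f s", name, timings[name])
    return result
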