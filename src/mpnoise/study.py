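"""Orchestration of the noise-robustness study and its reports.

A study takes one clean series, computes its matrix profile once, then for
each corruption condition in the grid: injects noise, recomputes the profile
on the corrupted series with the same window, aligns the two profiles with
FastDTW and records the summed absolute matched difference, the corrupted
profile's mean/max/min, and the normalised dissimilarity sum / (N * y1).

The standard grid is the ten conditions of the study design: duplication
factors k in {2..6} at a 5% anomaly fraction, and irrelevant-feature
proportions p in {1%, 5%, 10%, 25%, 50%}.  Every condition draws its own
seed, derived deterministically from the master seed and the condition
label, so adding conditions never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dtw import DTWParams, mp_dissimilarity
from .matrix_profile import MPConfig, compute_matrix_profile, mp_summary
from .noise import NoiseSpec, inject
from .series import TimeSeries

__all__ = [
    "StudyConfig",
    "StudyRow",
    "StudyReport",
    "default_grid",
    "derive_seed",
    "run_noise_study",
    "write_report",
    "read_report",
    "report_frame",
    "format_display",
    "load_study_config",
]

_log = logging.getLogger(__name__)

DUPLICATION_FACTORS = (2, 3, 4, 5, 6)
IRRELEVANT_PROPORTIONS = (0.01, 0.05, 0.10, 0.25, 0.50)

ORIGINAL_LABEL = "Original Matrix Profile"


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-condition seed below 2**31, from the master seed and label."""
    return zlib.crc32(f"{master_seed}|{label}".encode()) & 0x7FFFFFFF


def default_grid(master_seed: int = 0, anomaly_fraction: float = 0.05) -> list[NoiseSpec]:
    """The study's ten standard conditions, each with its own derived seed."""
    grid: list[NoiseSpec] = []
    for k in DUPLICATION_FACTORS:
        label = f"Duplicated Anomaly x{k}"
        grid.append(
            NoiseSpec(
                kind="duplicated_anomaly",
                factor=k,
                anomaly_fraction=anomaly_fraction,
                seed=derive_seed(master_seed, label),
            )
        )
    for p in IRRELEVANT_PROPORTIONS:
        label = f"Irrelevant Features {p:.0%}"
        grid.append(
            NoiseSpec(
                kind="irrelevant_features",
                proportion=p,
                anomaly_fraction=anomaly_fraction,
                seed=derive_seed(master_seed, label),
            )
        )
    return grid


@dataclass(frozen=True)
class StudyConfig:
    """Window, noise grid, DTW parameters and seeding for one study run."""

    window: int
    grid: tuple[NoiseSpec, ...] | None = None
    dtw: DTWParams = DTWParams(radius=30)
    master_seed: int = 0
    replicates: int = 1
    exclusion_radius: int | None = None

    def resolved_grid(self) -> list[NoiseSpec]:
        if self.grid is not None:
            return list(self.grid)
        return default_grid(self.master_seed)


@dataclass
class StudyRow:
    label: str
    sum_abs_diffs: float
    mean: float
    max: float
    min: float
    normalised: float
    seed: int
    replicates: int = 1
    iqr_normalised: float = 0.0


@dataclass
class StudyReport:
    """Machine-readable twin of the study's per-dataset result tables."""

    label: str
    n: int
    mp_length: int
    window: int
    y1: float
    rows: list[StudyRow]
    master_seed: int
    dtw_radius: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mp_length": self.mp_length,
            "window": self.window,
            "y1": self.y1,
            "master_seed": self.master_seed,
            "dtw_radius": self.dtw_radius,
            "rows": [dataclasses.asdict(r) for r in self.rows],
        }


def _reseeded(spec: NoiseSpec, seed: int) -> NoiseSpec:
    return dataclasses.replace(spec, seed=seed)


def run_noise_study(series: TimeSeries, config: StudyConfig) -> StudyReport:
    """Run the full study on one series and return its report.

    The first report row is the clean profile compared against itself (zero
    sum, zero normalised dissimilarity); one row follows per grid condition.
    With ``replicates > 1`` each condition is repeated under distinct derived
    seeds and the medians (plus normalised-dissimilarity IQR) are reported.
    """
    cfg = MPConfig(window=config.window, exclusion_radius=config.exclusion_radius)
    t0 = time.perf_counter()
    clean_mp = compute_matrix_profile(series, cfg)
    _log.info(
        "clean profile: n=%d m=%d length=%d (%.2fs)",
        series.n, config.window, len(clean_mp), time.perf_counter() - t0,
    )
    clean_sum = mp_summary(clean_mp)
    y1 = float(clean_mp.values.max())
    if y1 <= 0:
        raise ValueError("clean profile maximum is zero; dissimilarity undefined")
    rows = [
        StudyRow(
            label=ORIGINAL_LABEL,
            sum_abs_diffs=0.0,
            mean=clean_sum.mean,
            max=clean_sum.max,
            min=clean_sum.min,
            normalised=0.0,
            seed=config.master_seed,
        )
    ]
    for spec in config.resolved_grid():
        label = spec.label
        t0 = time.perf_counter()
        sums, means, maxs, mins, norms = [], [], [], [], []
        for r in range(config.replicates):
            seed = (
                spec.seed
                if config.replicates == 1
                else derive_seed(config.master_seed, f"{label}|rep{r}")
            )
            result = inject(series, _reseeded(spec, seed))
            noisy_mp = compute_matrix_profile(result.corrupted, cfg)
            diss = mp_dissimilarity(clean_mp, noisy_mp, config.dtw)
            s = mp_summary(noisy_mp)
            sums.append(diss.sum_abs_diffs)
            means.append(s.mean)
            maxs.append(s.max)
            mins.append(s.min)
            norms.append(diss.normalised)
        _log.info(
            "condition %s: %d replicate(s), median normalised %.4f (%.2fs)",
            label, config.replicates, float(np.median(norms)), time.perf_counter() - t0,
        )
        q25, q75 = np.percentile(norms, [25, 75])
        rows.append(
            StudyRow(
                label=label,
                sum_abs_diffs=float(np.median(sums)),
                mean=float(np.median(means)),
                max=float(np.median(maxs)),
                min=float(np.median(mins)),
                normalised=float(np.median(norms)),
                seed=spec.seed,
                replicates=config.replicates,
                iqr_normalised=float(q75 - q25),
            )
        )
    return StudyReport(
        label=series.label,
        n=series.n,
        mp_length=len(clean_mp),
        window=config.window,
        y1=y1,
        rows=rows,
        master_seed=config.master_seed,
        dtw_radius=config.dtw.radius,
    )


def report_frame(report: StudyReport) -> pd.DataFrame:
    """Report rows as a DataFrame in the canonical column order."""
    return pd.DataFrame(
        [
            {
                "condition": r.label,
                "sum_abs_diffs": r.sum_abs_diffs,
                "mean": r.mean,
                "max": r.max,
                "min": r.min,
                "normalised": r.normalised,
            }
            for r in report.rows
        ]
    )


def format_display(value: float) -> str:
    """Three-decimal display formatting used in the dissimilarity table."""
    return f"{value:.3f}"


def write_report(report: StudyReport, out_dir, fmt: str = "both") -> dict[str, Path]:
    """Write a report as CSV (table-shaped) and/or JSON (full precision).

    The CSV mirrors the result-table column order (Σ of absolute differences,
    then mean/max/min, then the normalised dissimilarity); the JSON carries
    full precision plus every seed needed for an exact re-run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = report.label.replace(" ", "_").replace("/", "-")[:60] or "study"
    paths: dict[str, Path] = {}
    if fmt in ("csv", "both"):
        csv_path = out_dir / f"{stem}.csv"
        report_frame(report).to_csv(csv_path, index=False)
        paths["csv"] = csv_path
        disp = report_frame(report).copy()
        for col in ("sum_abs_diffs", "mean", "max", "min", "normalised"):
            disp[col] = disp[col].map(format_display)
        disp_path = out_dir / f"{stem}_display.csv"
        disp.to_csv(disp_path, index=False)
        paths["display_csv"] = disp_path
    if fmt in ("json", "both"):
        json_path = out_dir / f"{stem}.json"
        json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        paths["json"] = json_path
    return paths


def read_report(json_path) -> StudyReport:
    d = json.loads(Path(json_path).read_text())
    rows = [StudyRow(**r) for r in d["rows"]]
    return StudyReport(
        label=d["label"],
        n=d["n"],
        mp_length=d["mp_length"],
        window=d["window"],
        y1=d["y1"],
        rows=rows,
        master_seed=d["master_seed"],
        dtw_radius=d["dtw_radius"],
    )


def load_study_config(yaml_path) -> StudyConfig:
    """Load a :class:`StudyConfig` from a YAML file.

    Recognised keys: ``window``, ``dtw_radius``, ``master_seed``,
    ``replicates``, ``exclusion_radius`` and an optional ``grid`` list of
    noise-spec mappings (``kind``, ``factor``/``proportion``, ...).
    """
    import yaml

    d = yaml.safe_load(Path(yaml_path).read_text())
    grid = None
    if "grid" in d and d["grid"] is not None:
        grid = tuple(NoiseSpec(**item) for item in d["grid"])
    return StudyConfig(
        window=int(d["window"]),
        grid=grid,
        dtw=DTWParams(radius=int(d.get("dtw_radius", 30))),
        master_seed=int(d.get("master_seed", 0)),
        replicates=int(d.get("replicates", 1)),
        exclusion_radius=d.get("exclusion_radius"),
    )
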