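"""Additive noise corruption for time series, with full provenance.

Two corruption schemes are implemented, both purely additive (no original
point is removed or reordered):

``duplicated_anomaly``
    A randomly selected fraction (default 5%) of the original points is
    designated anomalous and each such value is made to appear ``k`` times in
    the corrupted series.  By default the ``k - 1`` extra copies sit
    immediately after the original occurrence, creating a short constant run
    — the pattern a profile-based detector will pick up as a motif.  A
    ``scattered`` placement mode distributes the copies uniformly at random
    instead.

``irrelevant_features``
    ``floor(p * n)`` values drawn i.i.d. from the continuous uniform
    distribution on ``[min(X), max(X)]`` (bounds from the clean series) are
    inserted at slots chosen uniformly among the ``n + 1`` gaps, with
    replacement.

Every injection returns an :class:`InjectionResult` whose recorded insertion
positions let the exact original series be recovered by deletion — the
invariant the test suite leans on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

_log = logging.getLogger(__name__)

from .series import TimeSeries

__all__ = [
    "NoiseSpec",
    "InjectionResult",
    "inject",
    "inject_duplicated_anomalies",
    "inject_irrelevant_features",
    "write_injection",
]

KINDS = ("duplicated_anomaly", "irrelevant_features")
PLACEMENTS = ("adjacent", "scattered")


@dataclass(frozen=True)
class NoiseSpec:
    """Full parameterisation of one corruption condition.

    Parameters
    ----------
    kind
        ``"duplicated_anomaly"`` (uses ``factor``) or
        ``"irrelevant_features"`` (uses ``proportion``).
    factor
        Duplication multiplicity ``k >= 1``: each anomalous value appears
        ``k`` times in total.
    proportion
        Fraction ``p`` of the original length to insert as uniform draws.
    anomaly_fraction
        Fraction of original points designated anomalous (default 0.05).
    seed
        Fully determines the injection outcome.
    placement
        Where duplicate copies go: ``"adjacent"`` (default) or
        ``"scattered"``.
    anomaly_seed
        Optional separate seed for the anomaly-position draw, so the same
        anomaly set can be shared across duplication factors in paired
        comparisons.
    """

    kind: str
    factor: int | None = None
    proportion: float | None = None
    anomaly_fraction: float = 0.05
    seed: int = 0
    placement: str = "adjacent"
    anomaly_seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {KINDS}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0.0 < self.anomaly_fraction < 1.0:
            raise ValueError("anomaly_fraction must lie in (0, 1)")
        if self.kind == "duplicated_anomaly":
            if self.factor is None or int(self.factor) != self.factor or self.factor < 1:
                raise ValueError("duplicated_anomaly requires an integer factor k >= 1")
        else:
            if self.proportion is None or not 0.0 <= self.proportion <= 1.0:
                raise ValueError("irrelevant_features requires proportion p in [0, 1]")

    @property
    def label(self) -> str:
        if self.kind == "duplicated_anomaly":
            return f"Duplicated Anomaly x{self.factor}"
        return f"Irrelevant Features {self.proportion:.0%}"


@dataclass
class InjectionResult:
    """Corrupted series plus the 0-based positions of every inserted point.

    Deleting ``inserted_positions`` from ``corrupted`` recovers the original
    series exactly.
    """

    corrupted: TimeSeries
    inserted_positions: np.ndarray
    source: NoiseSpec

    def __post_init__(self) -> None:
        self.inserted_positions = np.asarray(self.inserted_positions, dtype=np.int64)

    def recover_original(self) -> np.ndarray:
        return np.delete(self.corrupted.values, self.inserted_positions)


def inject(series: TimeSeries, spec: NoiseSpec) -> InjectionResult:
    """Dispatch to the injector matching ``spec.kind``."""
    if spec.kind == "duplicated_anomaly":
        return inject_duplicated_anomalies(series, spec)
    return inject_irrelevant_features(series, spec)


def _insert_values(x: np.ndarray, slots: np.ndarray, values: np.ndarray):
    """Insert ``values[t]`` before original index ``slots[t]``; stable within a slot.

    Returns the new array and the positions of the inserted values in it.
    """
    order = np.argsort(slots, kind="stable")
    s = slots[order]
    v = values[order]
    out = np.insert(x, s, v)
    positions = s + np.arange(s.size)
    return out, positions


def inject_duplicated_anomalies(series: TimeSeries, spec: NoiseSpec) -> InjectionResult:
    """Duplicate a random 5% (by default) of values to appear ``k`` times each.

    Output length is ``n + (k - 1) * floor(anomaly_fraction * n)``; original
    order is preserved.
    """
    if spec.kind != "duplicated_anomaly":
        raise ValueError(f"spec kind is {spec.kind!r}")
    x = series.values
    n = x.size
    k = int(spec.factor)
    count = math.floor(spec.anomaly_fraction * n)
    if k > 1 and count < 1:
        raise ValueError(
            f"anomaly_fraction {spec.anomaly_fraction} selects no points from n={n}"
        )
    sel_rng = np.random.default_rng(
        spec.seed if spec.anomaly_seed is None else spec.anomaly_seed
    )
    pos = np.sort(sel_rng.choice(n, size=count, replace=False))
    if k == 1 or count == 0:
        return InjectionResult(
            corrupted=series.with_values(x.copy(), label=f"{series.label} | {spec.label}"),
            inserted_positions=np.empty(0, dtype=np.int64),
            source=spec,
        )
    if spec.placement == "adjacent":
        reps = np.ones(n, dtype=np.int64)
        reps[pos] = k
        out = np.repeat(x, reps)
        # position of selected original p shifts by (k-1) per earlier selection
        starts = pos + (k - 1) * np.arange(count)
        inserted = (starts[:, None] + np.arange(1, k)[None, :]).ravel()
    else:
        rng = np.random.default_rng(spec.seed)
        values = np.repeat(x[pos], k - 1)
        slots = rng.integers(0, n + 1, size=values.size)
        out, inserted = _insert_values(x, slots, values)
    corrupted = series.with_values(out, label=f"{series.label} | {spec.label}")
    return InjectionResult(corrupted=corrupted, inserted_positions=inserted, source=spec)


def write_injection(result: InjectionResult, path) -> None:
    """Export a corrupted series with its mask as CSV (value, is_inserted)."""
    import pandas as pd

    flags = np.zeros(result.corrupted.n, dtype=np.int64)
    flags[result.inserted_positions] = 1
    pd.DataFrame({"value": result.corrupted.values, "is_inserted": flags}).to_csv(
        path, index=False
    )


def inject_irrelevant_features(series: TimeSeries, spec: NoiseSpec) -> InjectionResult:
    """Insert ``floor(p*n)`` uniform draws from ``[min(X), max(X)]`` at random gaps."""
    if spec.kind != "irrelevant_features":
        raise ValueError(f"spec kind is {spec.kind!r}")
    x = series.values
    n = x.size
    p = float(spec.proportion)
    count = math.floor(p * n)
    rng = np.random.default_rng(spec.seed)
    if count == 0:
        return InjectionResult(
            corrupted=series.with_values(x.copy(), label=f"{series.label} | {spec.label}"),
            inserted_positions=np.empty(0, dtype=np.int64),
            source=spec,
        )
    if n < 2:
        raise ValueError("need at least two points to define uniform bounds")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        _log.warning(
            "degenerate series (min == max == %g): every insertion equals that constant", lo
        )
    values = rng.uniform(lo, hi, size=count)
    slots = rng.integers(0, n + 1, size=count)
    out, inserted = _insert_values(x, slots, values)
    corrupted = series.with_values(out, label=f"{series.label} | {spec.label}")
    return InjectionResult(corrupted=corrupted, inserted_positions=inserted, source=spec)
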