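#!/usr/bin/env python
"""Generate the three synthetic case-study series and record their vitals.

Writes each series to scratch/data/ (consumed by the later drivers) and a
small overview table to results/series_overview.csv.
"""

import pandas as pd

from mpnoise import generate, write_series

from _common import CASES, RESULTS, series_path


def main() -> None:
    rows = []
    for name, (spec, window) in CASES.items():
        result = generate(spec)
        series = result[0] if isinstance(result, tuple) else result
        path = series_path(name)
        path.parent.mkdir(parents=True, exist_ok=True)
        write_series(series, path)
        rows.append(
            {
                "name": name,
                "n": series.n,
                "window": window,
                "min": series.values.min(),
                "max": series.values.max(),
                "mean": series.values.mean(),
            }
        )
        print(
            f"{name:<12} n={series.n:>6}  range [{series.values.min():.2f}, "
            f"{series.values.max():.2f}]  -> {path.relative_to(path.parents[2])}"
        )
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "series_overview.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.4f")
    print(f"overview -> {out}")


if __name__ == "__main__":
    main()
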