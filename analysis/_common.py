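"""Shared definitions for the analysis drivers: the three case-study stand-ins.

The stand-ins mirror the structure of the three real datasets (inter-key
timings, calf activity, city traffic) at sizes that keep a full desktop run
in minutes: the traffic series is generated at its real length (3,600), the
two long series at reduced length (8,000 points; 7 days of minutes).
"""

from pathlib import Path

from mpnoise import GeneratorSpec

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"

# name -> (generator spec, matrix-profile window)
CASES = {
    "keystrokes": (GeneratorSpec(family="keystroke", n=8_000, seed=101), 20),
    "calf_amag": (GeneratorSpec(family="calf", duration_days=7, seed=202), 60),
    "traffic": (GeneratorSpec(family="traffic", n=3_600, seed=303), 24),
}

MASTER_SEED = 11


def series_path(name: str) -> Path:
    return SCRATCH / "data" / f"{name}.csv"


def profile_path(name: str) -> Path:
    return SCRATCH / "profiles" / f"{name}.csv"
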