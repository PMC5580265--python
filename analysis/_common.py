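"""Shared plumbing for the numbered analysis drivers.

Stage outputs go to results/; intermediate Python objects are cached in
scratch/ so each numbered script can pick up where the previous one left
off without recomputation.
"""

from __future__ import annotations

import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def save_stage(name: str, obj) -> None:
    SCRATCH.mkdir(exist_ok=True)
    with open(SCRATCH / f"{name}.pkl", "wb") as fh:
        pickle.dump(obj, fh)


def load_stage(name: str):
    path = SCRATCH / f"{name}.pkl"
    if not path.exists():
        sys.exit(
            f"missing cached stage {name!r} - run the earlier numbered scripts first"
        )
    with open(path, "rb") as fh:
        return pickle.load(fh)


def results_dir(sub: str) -> Path:
    out = RESULTS / sub
    out.mkdir(parents=True, exist_ok=True)
    return out
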