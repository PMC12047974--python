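"""Shared setup for the numbered analysis scripts.

Every script regenerates what it needs from the same deterministic smoke-scale
configuration (seed 0, ~107 subjects, 100 parcels), so the scripts can be run
independently and in any order. Small result tables go to results/; bulky
per-subject intermediates (time series, parcel-wise score tables) go under
scratch/, which is disposable.
"""

from pathlib import Path

from fcgrad.pipeline import smoke_config

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 0


def config(effects: bool = True):
    return smoke_config(seed=SEED, effects=effects)


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
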