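"""Shared study definition for the numbered analysis drivers.

One seeded simulated knockout-vs-control study (default configuration,
seed 1); every driver regenerates what it needs deterministically from this
config, so the scripts can be run independently and in any order.
"""

from pathlib import Path

from chromintegrate.simulate import SimulationConfig

STUDY = SimulationConfig(seed=1)
RESULTS = Path(__file__).resolve().parent.parent / "results"


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
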