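"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from plastisphere_n2o.pipeline import stage_seeds

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def parse_args(description: str) -> argparse.Namespace:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=42, help="global scenario seed")
    p.add_argument("--out", type=Path, default=RESULTS, help="results directory")
    return p.parse_args()


def seeds_for(seed: int) -> dict:
    return stage_seeds(seed)
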