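"""Shared paths and the study seed for the analysis scripts."""

import os

SEED = 1
ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
SIM = os.path.join(RESULTS, "sim")


def ensure(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path


def need_sim() -> str:
    if not os.path.exists(os.path.join(SIM, "genes.gtf")):
        raise SystemExit("run analysis/01_simulate.py first")
    return SIM
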