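#!/usr/bin/env python
"""Simulate a cumate-style dose-response experiment.

Generates stochastic switching trajectories (3 technical replicates at each
of 4 inducer concentrations, 7 time points over 8 h, gated counts out of
20,000 cells) with Hill-map ground-truth rates, and writes the trajectory
table plus ground truth under results/dose_response/.
"""

import json
from pathlib import Path

import pandas as pd

from loxkit.pipeline import make_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "dose_response"


def main() -> None:
    truth = make_fixtures("cumate_dose_response", seed=1, outdir=OUT)
    df = pd.read_csv(OUT / "trajectories.csv")
    print(f"wrote {len(df)} trajectory rows to {OUT/'trajectories.csv'}")
    print("ground-truth rates (per hour):")
    print(json.dumps(truth["k_by_concentration"], indent=2))


if __name__ == "__main__":
    main()
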