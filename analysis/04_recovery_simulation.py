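#!/usr/bin/env python
"""Parameter-recovery validation of the correction + incidence estimator.

Simulates 500 registries at the Dutch study scale (2.94M children, 48
months, true incidence 1.2 per 100,000 child-years, 89 hospitals at 90%
response), runs the full correction + incidence pipeline on each, and
reports the estimator's relative bias and the empirical coverage of the 95%
Monte Carlo interval.  Expected outcome: |bias| well under 3% and coverage
near 95%.
"""

import json
from dataclasses import asdict
from pathlib import Path

from ins_incidence.synthdata import SimulationConfig, recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20180101


def main() -> None:
    summary = recovery_experiment(
        SimulationConfig(), n_replicates=500, seed=SEED, n_sims=1000
    )
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "recovery.json").write_text(json.dumps(asdict(summary), indent=2) + "\n")
    print(json.dumps(asdict(summary), indent=2))


if __name__ == "__main__":
    main()
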