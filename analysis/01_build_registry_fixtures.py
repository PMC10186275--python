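#!/usr/bin/env python
"""Write the reconstructed cohort registries to CSV.

Builds the case-level reconstructions of the Dutch (2018-2021) and
Paris-area (2017-2021) INS cohorts from the published aggregate margins and
writes the four input schemas (cases, population, survey, measures) under
results/fixtures/.
"""

from pathlib import Path

from ins_incidence.fixtures import netherlands_registry, paris_registry, write_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    for inputs in (netherlands_registry(), paris_registry()):
        paths = write_fixture(inputs, OUT / inputs.region)
        boys = sum(c.sex == "male" for c in inputs.cases)
        print(
            f"{inputs.region}: {len(inputs.cases)} cases ({boys} boys), "
            f"{inputs.survey.units_surveyed} hospitals at response rate "
            f"{inputs.survey.response_rate:.2f} -> {paths['cases']}"
        )


if __name__ == "__main__":
    main()
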