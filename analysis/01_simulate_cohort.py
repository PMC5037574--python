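#!/usr/bin/env python
"""Simulate the default two-group NMR cohort and write it to results/cohort/.

Ten replicates per group, 36 metabolites, 14 of them perturbed in the
resistant-analogue (ER) group — including a GSH decrease. Prints the planted
change set so later stages can be checked against it.
"""

from pathlib import Path

from metabodisc import io as mio
from metabodisc.simulate import default_assignments, default_cohort_scenario, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 1


def main() -> None:
    scenario = default_cohort_scenario(seed=SEED)
    spectra, labels, truth = simulate_cohort(scenario)
    ids = [f"{lab}{i % scenario.n_per_group + 1:02d}" for i, lab in enumerate(labels)]

    OUT.mkdir(parents=True, exist_ok=True)
    prov = {"seed": SEED}
    mio.write_spectra_csv(OUT / "spectra.csv", spectra, ids, prov)
    mio.write_metadata_csv(OUT / "metadata.csv", ids, labels, prov)
    mio.write_ground_truth_csv(OUT / "ground_truth.csv", truth, ids, prov)
    mio.write_assignments_csv(OUT / "assignments.csv", default_assignments(scenario.library))

    ups = sorted(n for n, d in truth.perturbed_set if d == "increase")
    downs = sorted(n for n, d in truth.perturbed_set if d == "decrease")
    print(f"simulated {len(spectra)} spectra ({scenario.n_per_group}/group, "
          f"{len(scenario.library)} metabolites, seed {SEED}) -> {OUT}")
    print(f"planted increases ({len(ups)}): {', '.join(ups)}")
    print(f"planted decreases ({len(downs)}): {', '.join(downs)}")


if __name__ == "__main__":
    main()
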