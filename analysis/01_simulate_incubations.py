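#!/usr/bin/env python
"""Simulate the three spiked slurry incubation designs and record truth.

Emulates the experimental designs: a 1 mM sulfide spike into a 1:100
slurry (1 g sediment, 99 mL buffer, 10-min sampling), a 200 µM
thiosulfate spike into 20 g sediment / 20 mL buffer, and a 500 µM sulfite
spike into 1 g / 9 mL, each with three replicates, a heat-killed control
and a blank. Writes time courses, setup sidecars, and the true rates to
results/incubations/.
"""

from pathlib import Path

from sulfurcycle.io import write_json, write_timecourse
from sulfurcycle.synthetic import IncubationSimParams, simulate_incubation

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "incubations"

DESIGNS = {
    "sulfide_spike": IncubationSimParams(),
    "thiosulfate_spike": IncubationSimParams(
        species="thiosulfate",
        initial_conc_uM=200.0,
        sediment_g=20.0,
        liquid_L=0.020,
        chemical_rate=0.01,
        biological_rate=0.05,
        product_split={"zerovalent_sulfur": 0.1, "sulfate": 0.9},
        noise_sd_uM=10.0,
        timepoints=(0.0, 0.5, 1.0, 2.0, 3.0),
    ),
    "sulfite_spike": IncubationSimParams(
        species="sulfite",
        initial_conc_uM=500.0,
        sediment_g=1.0,
        liquid_L=0.009,
        chemical_rate=1.34,
        biological_rate=11.76,
        product_split={"sulfate": 1.0},
        noise_sd_uM=25.0,
        timepoints=(0.0, 1 / 3, 2 / 3, 1.0),
    ),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, params in DESIGNS.items():
        panel, truth = simulate_incubation(params, seed=SEED)
        write_timecourse(panel, OUT / f"{name}.tsv", OUT / f"{name}_setup.json")
        write_json(truth, OUT / f"{name}_truth.json")
        fi = truth["first_interval"]
        print(
            f"{name}: true first-interval total consumption "
            f"{fi['total_consumption']:.2f} µmol/h/g "
            f"(chemical {fi['chemical_consumption']:.2f})"
        )
    print(f"wrote {len(DESIGNS)} simulated incubations to {OUT}")


if __name__ == "__main__":
    main()
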