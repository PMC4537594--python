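#!/usr/bin/env python
"""Simulate every input of the study: a spiked proteome, paired tumor/control
ion maps for the three discovery platforms, a serum verification cohort, and
paired serum/plasma draws.

Writes ion-map TSVs, cohort CSV and ground truth JSON under results/sim/.
"""

import json
from pathlib import Path

from ionpanel import io as pio
from ionpanel import synth

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    proteome = synth.generate_proteome(
        300, 0.1, synth.ProteomeConfig(seed=SEED, differential_fold=8.0)
    )
    n_spiked = sum(p.true_fold_change > 1 for p in proteome)
    print(f"proteome: {len(proteome)} proteins, {n_spiked} spiked at 8x")
    for k, platform in enumerate(synth.PLATFORMS):
        cfg = synth.MapSimConfig(
            n_pairs_per_platform=4, platform=platform, noise_sd=0.25,
            seed=SEED * 10 + k,
        )
        maps = synth.generate_platform_experiment(proteome, cfg)
        pio.write_ion_maps(maps, OUT / f"maps_{platform}.tsv", seed=SEED, config=cfg)
        n_ions = sum(len(m.ions) for m in maps)
        print(f"  {platform}: {len(maps)} maps, {n_ions} ions total")
    truth = {
        p.accession: {"fold": p.true_fold_change, "localization": p.localization,
                      "n_eligible_peptides": sum(p.eligible)}
        for p in proteome
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    cohort = synth.generate_serum_cohort(
        synth.CohortSimConfig(
            marker_params=synth.default_marker_params(("SLPI",)), seed=SEED
        )
    )
    pio.write_table(cohort, OUT / "cohort.csv", sep=",", seed=SEED)
    print(f"serum cohort: {len(cohort)} subjects "
          f"({(cohort.label == 'case').sum()} cases / "
          f"{(cohort.label == 'control').sum()} controls), SLPI forced null")
    paired = synth.generate_paired_serum_plasma(10, concordance_sd=0.1, seed=SEED)
    pio.write_table(paired, OUT / "serum_plasma.csv", sep=",", seed=SEED)
    print("paired serum/plasma draws for 10 subjects written")


if __name__ == "__main__":
    main()
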