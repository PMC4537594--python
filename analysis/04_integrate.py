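#!/usr/bin/env python
"""Integrate candidates across the three platforms.

Two views are reported: (a) the Venn partition of the candidates recovered
from the simulation of scripts 01-03, and (b) the packaged 179-marker
membership fixture whose region counts reconstruct the published
per-platform totals, with its protein-class summary.
"""

import json
from pathlib import Path

from ionpanel import io as pio
from ionpanel import synth
from ionpanel.integrate import (
    integrate_platforms,
    round_half_up_percent,
    summarize_protein_classes,
    venn_partition,
)
from ionpanel.synth import PLATFORMS

ROOT = Path(__file__).resolve().parent.parent / "results"


def report(part, label):
    print(f"{label}: total {part.total}; per-platform {part.per_platform_totals}")
    print(f"  exactly one platform: {part.exactly_one} ({part.exactly_one_pct} %)")
    print(f"  all three platforms:  {part.all_three} ({part.all_three_pct} %)")


def main() -> None:
    (ROOT / "integrate").mkdir(parents=True, exist_ok=True)
    per_platform = {}
    for platform in PLATFORMS:
        audit = pio.read_table(ROOT / "discover" / f"candidates_{platform}.tsv")
        per_platform[platform] = audit[audit["selected"]]
    membership = integrate_platforms(per_platform)
    sim_part = venn_partition(membership)
    report(sim_part, "simulated candidates")

    fixture = synth.generate_discovery_fixture()
    fx_part = venn_partition(fixture)
    report(fx_part, "packaged membership fixture")
    cm_cl = int((fixture["cell_line"] & fixture["conditioned_medium"]).sum())
    matched = int(fixture["same_cell_line"].sum())
    print(f"  CM x cell-line markers resolved in the same line: "
          f"{matched}/{cm_cl} ({round_half_up_percent(matched, cm_cl)} %)")
    table, coverage = summarize_protein_classes(fixture, synth.fixture_annotations(), "all")
    print(f"  protein-class annotation coverage: {coverage} %")
    pio.write_table(table, ROOT / "integrate" / "class_summary.csv", sep=",")
    out = {
        "simulated": {"+".join(k): v for k, v in sim_part.region_counts.items()},
        "fixture": {"+".join(k): v for k, v in fx_part.region_counts.items()},
        "fixture_exactly_one_pct": fx_part.exactly_one_pct,
        "fixture_all_three_pct": fx_part.all_three_pct,
        "fixture_class_coverage_pct": coverage,
    }
    (ROOT / "integrate" / "venn.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
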