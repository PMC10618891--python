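"""Peripheral habitat loss drives the interior dominant extinct first.

Takes the canonical coexisting two-species pair (superior competitor and
disperser vs inferior at both) on a rasterized island, erodes the domain
boundary in increasing depths, and re-runs each eroded patch to
equilibrium. Counterintuitively, the competitively dominant interior
species — not the edge specialist that lives in the habitat being
removed — is lost first: it needs habitat far from the absorbing
boundary, and erosion brings the boundary to it everywhere at once.

Writes results/habitat_loss.csv (depth, interior area, per-species
survival).
"""

from pathlib import Path

import numpy as np

from patchcoex import (
    Ecosystem,
    IslandRecipe,
    SimulationConfig,
    generate_island,
    habitat_loss_experiment,
    rasterize,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    island = generate_island(IslandRecipe(macro_amp=0.2, micro_amp=0.01, seed=11))
    domain = rasterize(island, 64)
    # in 2-D the extra boundary demands a larger competitive edge than the
    # 1-D profile's a21 = 1.2 for the pair to coexist at depth 0
    eco = Ecosystem.two_species(a21=1.4, D1=3e-3, D2=5e-4)
    depths = np.linspace(0.0, 0.28, 8)
    table = habitat_loss_experiment(
        domain, eco, depths, config=SimulationConfig(max_steps=400_000)
    )
    table.to_csv(RESULTS / "habitat_loss.csv", index=False)
    print(table.to_string(index=False))
    d1 = table.loc[~table.sp1_survives, "depth"].min()
    d2 = table.loc[~table.sp2_survives, "depth"].min()
    print(f"\ninterior dominant (sp1) extinct from depth {d1:g}; "
          f"boundary specialist (sp2) from depth {d2:g}")

if __name__ == "__main__":
    main()
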