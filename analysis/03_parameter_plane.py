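"""Two-species outcome over the competition-dispersal parameter plane.

Scans a grid of competitive asymmetry a21 (with a12 = 1/a21) against
species 2's dispersal D2 at fixed D1, labelling each equilibrium
{coexist, sp1-only, sp2-only, both-extinct}. The printed grid shows the
structure of the coexistence region: none on the competitively neutral
line a21 = 1 (the inferior disperser excludes the superior), none in the
classic trade-off quadrants (superior competitor, inferior disperser),
coexistence only where the competitive and dispersal hierarchies align.

Writes results/parameter_plane.csv.
"""

from pathlib import Path

from patchcoex import scan_parameter_plane

RESULTS = Path(__file__).resolve().parents[1] / "results"

A21_VALUES = [0.67, 1.0, 1.2, 1.4, 2.0]
D2_VALUES = [3e-4, 1e-3, 3e-3, 6e-3, 1.2e-2]
D1 = 2e-3

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = scan_parameter_plane(A21_VALUES, D2_VALUES, D1=D1)
    table.to_csv(RESULTS / "parameter_plane.csv", index=False)
    grid = table.pivot(index="D2", columns="a21", values="label")
    print(f"D1 = {D1}; rows D2, columns a21 (a12 = 1/a21):")
    print(grid.to_string())
    print(f"\nwrote {RESULTS/'parameter_plane.csv'}")

if __name__ == "__main__":
    main()
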