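"""Build the synthetic study world and write its layers and tables.

Produces, under results/world/: one ESRI ASCII grid per landscape layer, the
historical transition-rate table, the age-to-carbon lookup, and a manifest
recording every seed.  This world (20x20 cells, 3 ecoregions, 6 counties) is
the shared input for the scenario analyses that follow.
"""

from pathlib import Path

from landcarbon import io
from landcarbon.world import make_world

OUT = Path(__file__).resolve().parents[1] / "results" / "world"
SEED = 2001


def main() -> None:
    world = make_world(seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_landscape_layers(world.grid, OUT / "landscape")
    world.history.to_csv(OUT / "rate_history.csv", index=False)
    # thinned age grid for the written table; the in-memory lookup is annual
    world.lookup[world.lookup.age % 10 == 0].to_csv(OUT / "age_carbon_lookup.csv", index=False)
    io.write_manifest(
        OUT / "manifest.json",
        seed=SEED,
        n_rows=world.grid.n_rows,
        n_cols=world.grid.n_cols,
        ecoregions=len(world.grid.ecoregions),
        counties=len(world.grid.counties),
        climate_variants=[f"{g}/{r}" for g, r in world.climate],
    )
    counts = world.grid.to_frame()["state_class"].value_counts()
    print(f"world written to {OUT}")
    print("land-cover mix (cells):")
    print(counts.to_string())


if __name__ == "__main__":
    main()
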