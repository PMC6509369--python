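"""Simulate a synthetic island population and its mark-resight surveys.

Builds the default 49 x 1.5 km island (ponds clustered to the west), five
breeding seasons of band-structured horses, and the survey sighting table.
"""

from opsel import synth

ds = synth.simulate_dataset(synth.IslandConfig(seed=42))

print(f"ponds: {len(ds.island.ponds)}, island area {ds.island.area_km2} km²")
per_year = ds.population.groupby("year").size()
print("individuals per year:", dict(per_year))
counts = ds.sightings.groupby(["year", "individual_id"]).size()
print(f"sightings: {len(ds.sightings)} rows; repeat sightings per "
      f"individual mean {counts.mean():.2f}, SD {counts.std():.2f} "
      f"(field protocol: mean 2.84, SD 1.43)")
print(ds.sightings.head(4).to_string(index=False))
# Each row is one individual recorded at one survey occasion; all members
# of a band share the band's location for that occasion.
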