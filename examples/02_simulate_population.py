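"""Generate a synthetic forensic study population and inventory its alleles.

The generator emulates a 628-sample cohort (547 males / 81 females) typed
at 52 autosomal and 81 Y STRs, with iso-length sequence variants nested
inside length alleles.
"""

from strpopgen import SimConfig, allele_inventory, generate_dataset

table, truth = generate_dataset(SimConfig(seed=1))
print(f"samples: {len(table.samples)}  males: {len(table.males)}")
print(f"markers: {len(table.panel)} "
      f"({len(table.markers('autosomal'))} autosomal, {len(table.markers('y'))} Y)")

for level in ("length", "sequence"):
    inv = allele_inventory(table, level)
    t = inv.totals
    print(f"{level:>8s} level: {t['autosomal']} autosomal + {t['y']} Y "
          f"= {t['all']} distinct alleles")
# Sequence resolution reveals roughly 1.6x more alleles than length
# resolution: the extra alleles are iso-length variants invisible to CE.
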