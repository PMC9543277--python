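"""Partner-count summaries of a parasite-host interaction list.

Generates a synthetic global edge list at the documented scale (83 brood
parasite species with at least one known host) and prints the standard
species-level summary: median hosts per parasite, IQR, maximum, and the
fractions of species with more than one partner.
"""

import paranet as pn
from paranet.synthetic import WorldConfig, generate_interactions

config = WorldConfig(seed=2, n_parasites=83, n_hosts=1600)
table = generate_interactions(config)
summary = pn.species_summaries(table)
print(summary.report())
print()
print("The documented global system has median 11 hosts per parasite "
      "(IQR 24, max 274), with 82% of parasites using more than one host; "
      "the generator is calibrated to that degree distribution.")

# report which declared parasites would be excluded for lack of hosts
declared = set(table.parasite_ids) | {f"undocumented_{i}" for i in range(21)}
_, excluded = pn.drop_hostless_parasites(table, declared)
print(f"\n{len(excluded)} declared parasites have no documented host and "
      f"are excluded from mapping.")
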