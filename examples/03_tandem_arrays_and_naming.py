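"""Resolve a tandem island array and name its members.

Three islands stacked at one tDNA: each member carries its own integrase
gene and its own displaced tDNA fragment, which is the criterion for calling
a tandem array instead of collapsing to a single island.  Island names follow
the genus/species nickname + strain serial + length-in-kbp + site-letter
convention (e.g. a 49,591 bp island in a tRNA-Ser gene of strain Eco661 is
Eco661_50S).
"""

from tdna_islands import (
    Organism,
    PipelineConfig,
    PlantSpec,
    SyntheticPlan,
    generate,
    name_island,
)
from tdna_islands.pipeline import run_replicon

print("worked naming example:",
      name_island("Escherichia", "coli", 661, 49591, "Ser"), "\n")

plan = SyntheticPlan(
    seed=99,
    plants=[PlantSpec(kind="tandem_array", island_length=3000, crossover=53,
                      array_size=3)],
    organism=Organism("Synthetica", "exemplaris", "syn1"),
)
data = generate(plan)
result = run_replicon(
    data.replicon, data.tdnas, data.integrases, data.domains, PipelineConfig()
)
for isl in result.islands:
    k, n = isl.tandem_index
    print(
        f"{isl.name:<12} member {k} of {n}  "
        f"[{isl.interval.start}, {isl.interval.end})  {isl.length} bp  "
        f"integrases={isl.integrase_count}"
    )
# Members partition the span gene -> outermost fragment; each segment ends at
# its own fragment copy and contains its own integrase.
assert [i.tandem_index for i in result.islands] == [(1, 3), (2, 3), (3, 3)]
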