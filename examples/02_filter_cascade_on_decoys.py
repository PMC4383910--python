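"""Show each decoy class being rejected by exactly its designed filter.

Generates a replicon carrying nine decoy islands, one violating each filter
(no integrase, excluded Xer/integron integrase, fragment inside a conserved
protein domain, fragment inside another tDNA, too short, too long, internal
fragment, wrong-side configuration, opposite orientation), and prints the
filter that rejected each.
"""

from tdna_islands import PipelineConfig, PlantSpec, SyntheticPlan, generate, truth_compare
from tdna_islands.pipeline import run_replicon
from tdna_islands.simulate import DECOY_KINDS

plants = [
    PlantSpec(
        kind=k,
        island_length=201000 if k == "decoy_long" else 1500 if k == "decoy_short" else 4000,
        crossover=45,
    )
    for k in DECOY_KINDS
]
data = generate(SyntheticPlan(seed=7, plants=plants))
result = run_replicon(
    data.replicon, data.tdnas, data.integrases, data.domains, PipelineConfig(),
    evaluate_all=True,
)
report = truth_compare(
    result.islands, data.truth, candidates=result.candidates,
    replicon_length=len(data.replicon),
)

print(f"islands called from 9 decoys: {len(result.islands)} (should be 0)\n")
print(f"{'decoy class':<28} {'designed filter':<16} rejected by")
for r in sorted(report.decoy_reports, key=lambda r: r.plant_index):
    print(f"{r.kind:<28} {r.designed_filter:<16} {', '.join(r.failed_filters)}")
# Every decoy fails exactly the one filter it was built to violate; the other
# six filters all pass it, demonstrating the filters probe orthogonal signals.
assert report.all_decoys_rejected_at_designed_filter
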