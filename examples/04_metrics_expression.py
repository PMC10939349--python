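"""Occurrence, agreement and diagnostic metrics, plus expression roll-up.

Relative occurrence scales a KO's protein count to a per-million
frequency (N_select / N_total * 1e6).  The diagnostic formulas are
implemented exactly as published; because specificity = 1 - sensitivity
under those formulas, both likelihood ratios are identically 1 — the
`degenerate` flag makes that explicit.
"""

from pathlib import Path

from archannot import GeneratorConfig, generate_dataset, io, annotate_all
from archannot.metrics import (
    agreement_summary,
    cluster_expression,
    diagnostic_metrics,
    relative_occurrence,
)
from archannot.model import Domain
from archannot.partition import cluster_ko_sets, collect_ko_universe, \
    partition_by_ko

print("relative occurrence of a KO seen twice among 707754 proteins:",
      f"{relative_occurrence(2, 707754):.4f} per million")

m = diagnostic_metrics(3, 1)
print(f"diagnostics for 3 structure / 1 sequence correct calls: "
      f"sensitivity {m.sensitivity}, specificity {m.specificity}, "
      f"PLR {m.plr}, NLR {m.nlr} (degenerate: {m.degenerate})")

out = Path("scratch/example_bundle")
generate_dataset(GeneratorConfig(seed=7), out)
bundle = io.load_bundle(out)

table = annotate_all(bundle.evidence.values())
kbc = cluster_ko_sets(bundle.clusters.values(), bundle.ko)
bact = collect_ko_universe(bundle.clusters.values(), bundle.ko,
                           domain=Domain.BACTERIA)
result = partition_by_ko(bundle.superclusters_of_domain(Domain.ARCHAEA),
                         kbc, bact)
summary = agreement_summary(table, {sid: g.value
                                    for sid, g in result.group_of.items()})
print(summary[summary["count"] > 0].to_string(index=False))

membership = {sc.supercluster_id: [p for c in sc.member_cluster_ids
                                   for p in bundle.clusters[c].member_ids]
              for sc in bundle.superclusters_of_domain(Domain.ARCHAEA)}
expr = cluster_expression(bundle.coverage, membership)
high = [e.label for e in expr if e.high_expression]
print(f"high-expression superclusters (>= 75th percentile): {high}")
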