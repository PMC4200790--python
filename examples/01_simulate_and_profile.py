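"""Simulate a ground-truthed small-RNA library and profile its miRNAs.

Builds a toy genome with hairpin precursors, draws 20,000 reads from a
cell-like class mixture, runs the full pipeline (trim, collapse, annotate,
isomiR quantification) and prints the composition table plus the top
expressed miRNAs, comparing the recovered counts against the simulator's
ground truth.
"""

import exomir as ex

config = ex.SimulationConfig(seed=42, reads_per_library=20_000)
refs = ex.build_reference(config)
reads, truth = ex.simulate_reads(refs, config, "cells")

result = ex.run_library(
    "cells",
    (seq for _, seq in reads),
    refs.precursors,
    refs.class_refs,
    ex.PipelineConfig(min_count=1),
)

print(f"clean reads:     {result.summary.clean_read_count}")
print(f"trimmed (15-32): {result.summary.trimmed_read_count}")
print(f"unique tags:     {result.summary.unique_tag_count}")
print()
print("Small-RNA class composition (unique tags / total reads, % of library):")
print(result.composition)
print()

top = sorted(result.profiles, key=lambda p: -p.total_count)[:5]
print("Top expressed miRNAs (count, RPM, representative isomiR):")
for p in top:
    true = truth.mirna_counts.get((p.mirna_id, p.arm), 0)
    print(
        f"  {p.key:12s} seed={p.seed} count={p.total_count:5d} "
        f"(truth {true:5d}) rpm={p.normalized_expression:9.1f} "
        f"isomiRs={len(p.isomirs)}"
    )
print()
print(
    "Each profile aggregates all isomiRs of one (precursor, arm); counts\n"
    "match the simulated truth up to reads lost to the 15-32 nt length\n"
    "filter, and RPM is the count per million trimmed reads."
)
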