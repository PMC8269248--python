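"""Assemble transcription units and clusters from TSSs, TEPs and coverage.

Every TSS x TEP combination is tested with the sliding-window coverage
criterion (200-bp windows, 5% of the region mean, raw floor of 5); accepted
pairs become TUs, overlapping TUs merge into TUCs, and members ending at a
cluster's 3'-most end are labeled terminal.
"""

import termscape as ts

genome, genes, tss_set, truth, termseq, rnaseq = ts.default_simulation(seed=1)
cfg = ts.PipelineConfig(cv_reps=0, rng_seed=1)
result = ts.run_pipeline(genome, genes, tss_set, termseq, rnaseq, cfg)

print(f"{len(result.tus)} TUs in {len(result.tucs)} TUCs")
print("TU categories:", result.summary["tu_by_category"])
for tuc in result.tucs[:5]:
    print(f"TUC {tuc.contig}:{tuc.start}-{tuc.end} ({tuc.strand}) "
          f"genes={','.join(tuc.gene_ids) or '-'}")
    for tu in tuc.members:
        print(f"   TU {tu.start}-{tu.end} {tu.category:<5} {tu.terminality:<11} "
              f"phases={','.join(tu.passing_phases)}")
# Mono = exactly one fully contained gene; a TU is reported only if at least
# one growth phase shows continuous coverage between its TSS and TEP.
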