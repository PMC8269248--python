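"""Classify 3' ends by upstream RNA structure and U-tract content.

Folds the 40-nt window upstream of each called end at 30 degC, parses the
3'-most hairpin out of the MFE structure, counts uridines in the 8-nt tract
downstream of the stem, and assigns HS-U-rich / HS-U-lack / LS labels.
"""

import termscape as ts

genome, genes, tss_set, truth, termseq, rnaseq = ts.default_simulation(seed=1)
cfg = ts.PipelineConfig(cv_reps=0, rng_seed=1)
result = ts.run_pipeline(genome, genes, tss_set, termseq, rnaseq, cfg)

truth_by_pos = {(t.contig, t.strand, t.position): t.tep_class
                for t in truth.teps}
print(f"{'position':>9} {'strand':>6} {'dG':>7} {'stem':>4} {'loop':>4} "
      f"{'U':>2}  class        planted")
for tep in sorted(result.teps, key=lambda t: t.position)[:10]:
    stem = tep.stem
    planted = truth_by_pos.get((tep.contig, tep.strand, tep.position), "?")
    print(f"{tep.position:>9} {tep.strand:>6} {tep.delta_g:>7.1f} "
          f"{stem.stem_length if stem else '-':>4} "
          f"{stem.loop_length if stem else '-':>4} "
          f"{tep.u_count:>2}  {tep.tep_class:<12} {planted}")
# dG below -23 kcal/mol marks a highly structured (HS) end; >=3 U in the
# tract downstream of the stem marks the classic intrinsic-terminator
# hairpin + U-tract (HS-U-rich). The last column shows the planted label.
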