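"""Generate a synthetic paired-biopsy cohort and normalize it to log2 expression.

The generator mirrors an 8-patient imiquimod-style design: paired pre/post
samples, 770 endogenous immune genes plus housekeeping and control probes,
with known log2 effects injected into the ICR and antigen-presentation genes
of responders.
"""

import icrprofiler as icp

counts, samples, truth = icp.generate_dataset(icp.SyntheticConfig(seed=1))
print(f"panel: {counts.counts.shape[0]} probes x {counts.counts.shape[1]} samples "
      f"({len(counts.panel.endogenous)} endogenous)")
print(f"cohort: {len(samples.pairs())} complete pre/post pairs; "
      f"responders = {', '.join(truth.responder_patients)}")

expr, report = icp.normalize_pipeline(counts)
factors = list(report.housekeeping_factor.values())
print(f"normalized matrix: {expr.data.shape}, "
      f"housekeeping factors {min(factors):.2f}-{max(factors):.2f}, "
      f"{report.n_clamped()} cells clamped at the background floor")
# The housekeeping factors absorb library-size differences between samples;
# clamped cells are low-expressed genes that fell below the negative-control
# background after subtraction.
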