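"""Probe-validity QC: in-silico bisulfite alignment and sequential filtering.

Builds the two bisulfite-converted reference strands (C→T forward, G→A
reverse), scans every probe for unique alignment, applies a SNP-in-CpG
mask, and filters a detection-P matrix.
"""

import numpy as np
import pandas as pd

import twinmeth as tm

manifest, reference = tm.generate_probe_manifest(
    n_total=500, n_multi=12, n_snp=6, n_candidate=30, seed=2
)

conv = tm.bisulfite_convert(reference)
print(f"reference: {conv.source_length} bp; forward strand contains no C: "
      f"{'C' not in conv.forward}")

# re-derive the multi-alignment flags by scanning, then filter sequentially
rescanned = tm.annotate_alignments(manifest, reference)
kept, report = tm.qc_filter(rescanned)
print(report.summary())
# Multi-alignment is applied first, SNP-in-CpG among the survivors; the
# three dispositions always partition the input exactly.

# detection-P masking: a cell at P = 0.05 is a failed measurement
beta, design, _ = tm.generate_twin_beta(
    manifest, tm.SimulationConfig(n_pairs=4, n_probes=500), seed=2
)
rng = np.random.default_rng(2)
detp = pd.DataFrame(
    rng.uniform(0, 0.2, beta.values.shape),
    index=beta.values.index, columns=beta.values.columns,
)
masked, counts = tm.apply_detection_filter(beta, detp, threshold=0.05)
print(f"masked beta values per sample (threshold 0.05, inclusive): "
      f"min {counts.min()}, max {counts.max()}")
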