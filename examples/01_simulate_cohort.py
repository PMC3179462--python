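"""Simulate a synthetic fiber-count cohort and write it to disk.

The generator emulates a longitudinal design: 39 subjects scanned at
three ages share one planted modular backbone; each scan adds
negative-binomial count noise, spurious low-count connections, and
lognormal fiber lengths whose mean rises with age.
"""

import tempfile
from pathlib import Path

import connectome_backbone as cb

cohort, backbone, modules = cb.sample_cohort(cb.CohortConfig(seed=1))

print(f"scans: {cohort.n_scans} ({len(cohort.groups())} age groups x 39 subjects)")
print(f"regions: {cohort.atlas.n_regions} (paired L/R cortical atlas)")
print(f"planted backbone: {backbone.n_edges} edges "
      f"(cost {backbone.n_edges / backbone.max_edges:.3f}), "
      f"{modules.max() + 1} ground-truth modules")

out = Path(tempfile.mkdtemp()) / "cohort"
cb.write_cohort(cohort, out)
back = cb.read_cohort_dir(out)
print(f"round-trip through {out}: {back.n_scans} scans, "
      f"counts identical: {(back.counts == cohort.counts).all()}")
# The planted backbone and module labels are the ground truth that the
# SNR thresholding and community detection steps are expected to recover.
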