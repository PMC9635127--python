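"""Generate a small synthetic PSSM cohort and inspect its shape.

The generator emulates what a real adaptor-protein PSSM collection looks
like statistically: wildly variable sequence lengths, a 1:9 class imbalance,
and integer log-odds scores in which positive profiles carry a few conserved
(elevated) residue columns over a short motif window.
"""

import numpy as np

from pssmformer import GeneratorConfig, generate_dataset, materialize_dataset

config = GeneratorConfig(n_pos=20, n_neg=180, seed=42)
dataset = generate_dataset(config)

lengths = np.array([p.length for p in dataset])
print(f"profiles: {len(dataset)}  (adaptors: {dataset.n_pos}, others: {dataset.n_neg})")
print(f"lengths:  min {lengths.min()}, median {int(np.median(lengths))}, "
      f"max {lengths.max()}")
first = dataset.profiles[0]
print(f"first profile {first.id!r}: {first.length} x 20 scores, label {first.label}")

manifest = materialize_dataset(dataset, "scratch/example_dataset")
print(f"materialized to {manifest.parent}/ (PSI-BLAST-style files + {manifest.name})")
# Each profile is an N x 20 integer log-odds matrix; the manifest CSV
# (id,path,label) is the handle every other command consumes.
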