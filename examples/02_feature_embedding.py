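"""Embed one protein into the d=30 feature space and show the column rules.

Each residue row is: 20 squashed PSSM log-odds, RSA, 3 secondary-structure
propensities, phi/psi over 360, two conservation scores, residue type
index/21, and position i/L.
"""

import numpy as np

from seqsite import (
    SimulationConfig,
    normalize_pssm,
    position_embeddings,
    simulate_corpus,
)
from seqsite.features import feature_map_from_record

corpus = simulate_corpus(SimulationConfig(n_proteins=1, length_range=(12, 12), seed=3))
protein = corpus.proteins[0]
fm = feature_map_from_record(protein)

print(f"protein {protein.id}: {protein.sequence} (L={len(protein)})")
print(f"feature map shape: {fm.values.shape}")
raw0 = protein.features[0, :20]
print(f"raw PSSM row 1 (first 5):      {np.round(raw0[:5], 3)}")
print(f"squashed 1/(1+2^-x) (first 5): {np.round(normalize_pssm(raw0)[:5], 3)}")
print(f"residue-type column: {np.round(fm.values[:, 28], 3)}")
print(f"position column i/L: {np.round(fm.values[:, 29], 3)}")
assert np.allclose(fm.values[:, 29], position_embeddings(len(protein)))
# The squashed PSSM stays strictly inside (0,1); a zero log-odds score maps
# to exactly 0.5, and the position column ends at exactly 1.0 (i = L).
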