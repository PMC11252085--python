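import numpy as np
import pandas as pd
import pytest

from quartetqc import OmicsDataset, SampleMeta


def make_dataset(values, donors, replicates=None, batch="B1", omics_type="rna",
                 feature_ids=None, batches=None, scale="absolute",
                 reference_donor=None):
    """Build a small OmicsDataset from a 2-D array and per-column labels."""
    values = np.asarray(values, float)
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    if replicates is None:
        counts = {}
        replicates = []
        for d in donors:
            counts[d] = counts.get(d, 0) + 1
            replicates.append(counts[d])
    if batches is None:
        batches = [batch] * n_samp
    samples = [
        SampleMeta(f"{d}_{b}_r{r}", d, r, b)
        for d, r, b in zip(donors, replicates, batches)
    ]
    frame = pd.DataFrame(values, index=feature_ids,
                         columns=[s.sample_id for s in samples])
    return OmicsDataset(values=frame, samples=samples, omics_type=omics_type,
                        scale=scale, reference_donor=reference_donor)


@pytest.fixture
def quartet_batch():
    """One batch, 4 donors x 3 replicates, 6 features, strong donor signal."""
    rng = np.random.default_rng(42)
    donors = [d for d in ("D5", "D6", "F7", "M8") for _ in range(3)]
    effects = {"D5": 0.0, "D6": 0.5, "F7": 2.0, "M8": -2.0}
    base = rng.normal(8, 1, (6, 1))
    values = base + np.array([[effects[d] for d in donors]]) + rng.normal(0, 0.1, (6, 12))
    return make_dataset(values, donors)
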