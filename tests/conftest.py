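import numpy as np
import pandas as pd
import pytest

from spoteval.io_model import FeatureTable


def make_table(values, feature_classes, sample_meta, **flags) -> FeatureTable:
    """Build a small validated FeatureTable from plain lists.

    values: 2-D array (features x samples);
    feature_classes: list of (feature_id, assay, compound_class);
    sample_meta: list of (sample_id, device, solvent, replicate, day, assay, mode).
    """
    fids = [f[0] for f in feature_classes]
    anno = pd.DataFrame(
        {"assay": [f[1] for f in feature_classes],
         "compound_class": [f[2] for f in feature_classes]},
        index=pd.Index(fids, name="feature_id"),
    )
    meta = pd.DataFrame(
        sample_meta,
        columns=["sample_id", "device", "solvent", "replicate", "day", "assay",
                 "extraction_mode"],
    ).set_index("sample_id")
    X = pd.DataFrame(np.asarray(values, dtype=float), index=anno.index,
                     columns=meta.index)
    return FeatureTable(X, anno, meta, **flags).validate()


@pytest.fixture
def toy_table() -> FeatureTable:
    """2 polar features x 3 replicate samples on one device/solvent."""
    return make_table(
        [[100.0, 50.0, 25.0], [3.0, 6.0, 0.0]],
        [("f1", "polar", "amino acids"), ("f2", "polar", "sugars")],
        [(f"S{r}", "Capitainer", "CH3OH100", r, 0, "both", "single") for r in (1, 2, 3)],
    )


def brute_force_scores(raw: np.ndarray) -> np.ndarray:
    """Independent if-chain reimplementation of the 0-4 extraction score.

    Enumerates every cell: relative % of the feature's row maximum, then
    explicit percentile-bin branches exactly as the scoring rule states.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.zeros(raw.shape, dtype=int)
    for i in range(raw.shape[0]):
        mx = raw[i].max()
        for j in range(raw.shape[1]):
            v = raw[i, j]
            if v == 0:
                out[i, j] = 0
                continue
            rel = v / mx * 100.0
            if rel < 25.0:
                out[i, j] = 1
            elif rel < 50.0:
                out[i, j] = 2
            elif rel < 75.0:
                out[i, j] = 3
            else:
                out[i, j] = 4
    return out
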