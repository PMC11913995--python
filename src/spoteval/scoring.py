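"""Extraction score: quartile-binned relative intensity, summed per sample.

For every feature, each sample's raw intensity is divided by the maximum
intensity of that feature over the in-scope samples and expressed as a
percentage.  The percentage is binned into a 0-4 score:

=====  =========================================
score  relative intensity
=====  =========================================
0      not detected (raw intensity exactly 0)
1      < 25%
2      25% <= x < 50%
3      50% <= x < 75%
4      >= 75%
=====  =========================================

The total score of an extraction condition is the sum of the per-feature
scores of one sample, averaged over replicates (mean +/- SD).  Class-level
heatmaps average per-feature scores over all features of a compound class
and all replicates of a (device, solvent) cell.

Scope of the per-feature maximum defaults to all samples sharing a device
and assay (solvents and replicates pooled), so devices are ranked
independently; ``scope="assay"`` pools devices as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ASSAYS,
    CLASSES_BY_ASSAY,
    SOLVENTS,
    FeatureTable,
    ValidationError,
)

BIN_EDGES = (25.0, 50.0, 75.0)  # lower-inclusive bin starts for scores 2, 3, 4


def relative_intensity(table: FeatureTable, sample_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-feature intensity as % of that feature's in-scope maximum.

    Features that are zero in every in-scope sample return 0% everywhere
    (no division by zero).  The table must hold raw intensities.
    """
    if table.normalized or table.log_transformed:
        raise ValidationError("relative intensity is defined on raw intensities")
    X = table.intensities if sample_ids is None else table.intensities[list(sample_ids)]
    if X.shape[1] == 0:
        raise ValidationError("empty sample scope")
    rowmax = X.max(axis=1)
    safe = rowmax.replace(0, np.nan)
    return (X.div(safe, axis=0) * 100.0).fillna(0.0)


def score_feature(rel_pct: float, detected: bool = True) -> int:
    """Score a single observation from its relative intensity percentage.

    ``detected=False`` encodes a raw intensity of exactly 0 and always
    scores 0; a detected signal scores at least 1 however small.
    """
    if not 0.0 <= rel_pct <= 100.0:
        raise ValidationError(f"relative intensity {rel_pct} outside [0, 100]")
    if not detected:
        return 0
    if rel_pct >= BIN_EDGES[2]:
        return 4
    if rel_pct >= BIN_EDGES[1]:
        return 3
    if rel_pct >= BIN_EDGES[0]:
        return 2
    return 1


def _score_block(raw: pd.DataFrame, rel: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of one scope block."""
    r = rel.to_numpy()
    if ((r < 0) | (r > 100)).any():
        raise ValidationError("relative intensities outside [0, 100]")
    scores = 1 + (r >= BIN_EDGES[0]).astype(np.int64) \
               + (r >= BIN_EDGES[1]).astype(np.int64) \
               + (r >= BIN_EDGES[2]).astype(np.int64)
    scores[raw.to_numpy() == 0] = 0
    return pd.DataFrame(scores, index=rel.index, columns=rel.columns)


@dataclass
class ScoreReport:
    """Scores at the three aggregation levels the workflow reports."""

    scores: pd.DataFrame  # features x samples; NaN where sample not in assay scope
    per_sample_totals: pd.DataFrame  # sample_id, assay, total
    condition_totals: pd.DataFrame  # device, solvent, assay, (day, mode), mean, sd
    heatmaps: dict[tuple[str, str], pd.DataFrame]  # (device, assay) -> class x solvent
    scope: str


def _scope_groups(table: FeatureTable, scope: str):
    """Yield (assay, group-label, feature_ids, sample_ids) scope blocks."""
    for assay in ASSAYS:
        feats = table.annotations.index[table.annotations["assay"] == assay]
        if len(feats) == 0:
            continue
        meta = table.samples[table.samples["assay"].isin([assay, "both"])]
        if len(meta) == 0:
            continue
        if scope == "device-assay":
            for device, sub in meta.groupby("device", sort=False):
                yield assay, device, feats, sub.index
        elif scope == "assay":
            yield assay, "all", feats, meta.index
        else:
            raise ValidationError(f"unknown scope {scope!r} (use 'device-assay' or 'assay')")


def score_table(table: FeatureTable, scope: str = "device-assay") -> ScoreReport:
    """Full score report for one experiment table.

    Relative intensities are computed within each scope block (by default
    all samples of one device and assay, pooling solvents, replicates,
    days and extraction modes present in the table).
    """
    if table.normalized or table.log_transformed:
        raise ValidationError("scoring is defined on raw intensities")
    table.validate()

    scores = pd.DataFrame(np.nan, index=table.feature_ids, columns=table.sample_ids)
    for assay, _, feats, sids in _scope_groups(table, scope):
        sub = table.subset_features(feats).subset_samples(sids)
        rel = relative_intensity(sub)
        scores.loc[feats, sids] = _score_block(sub.intensities, rel).to_numpy()

    # per-sample totals, one row per (sample, assay) actually scored
    rows = []
    anno = table.annotations
    for assay in ASSAYS:
        feats = anno.index[anno["assay"] == assay]
        if len(feats) == 0:
            continue
        block = scores.loc[feats]
        for sid in table.sample_ids:
            col = block[sid]
            if col.notna().any():
                rows.append(dict(sample_id=sid, assay=assay, total=int(col.sum())))
    per_sample = pd.DataFrame(rows, columns=["sample_id", "assay", "total"])

    # condition totals: mean +/- SD (n-1) over replicates
    meta = table.samples
    cond_rows = []
    if len(per_sample):
        merged = per_sample.merge(
            meta[["device", "solvent", "day", "extraction_mode"]],
            left_on="sample_id", right_index=True,
        )
        keys = ["device", "solvent", "assay", "day", "extraction_mode"]
        for key_vals, grp in merged.groupby(keys, sort=False):
            totals = grp["total"].to_numpy(dtype=float)
            single = len(totals) < 2
            cond_rows.append(
                dict(zip(keys, key_vals))
                | dict(
                    n_replicates=len(totals),
                    mean_score=float(totals.mean()),
                    sd_score=0.0 if single else float(totals.std(ddof=1)),
                    single_replicate=single,
                )
            )
    condition_totals = pd.DataFrame(
        cond_rows,
        columns=["device", "solvent", "assay", "day", "extraction_mode",
                 "n_replicates", "mean_score", "sd_score", "single_replicate"],
    )

    # class x solvent heatmap per (device, assay); NaN marks empty classes
    heatmaps: dict[tuple[str, str], pd.DataFrame] = {}
    for assay in ASSAYS:
        feats = anno.index[anno["assay"] == assay]
        if len(feats) == 0:
            continue
        meta_a = meta[meta["assay"].isin([assay, "both"])]
        classes = list(CLASSES_BY_ASSAY[assay])
        for device, sub in meta_a.groupby("device", sort=False):
            solvents = [s for s in SOLVENTS if s in set(sub["solvent"])]
            hm = pd.DataFrame(np.nan, index=pd.Index(classes, name="compound_class"),
                              columns=pd.Index(solvents, name="solvent"))
            for c in classes:
                cfeats = anno.index[(anno["assay"] == assay) & (anno["compound_class"] == c)]
                if len(cfeats) == 0:
                    continue  # flagged missing as NaN, never 0
                for s in solvents:
                    sids = sub.index[sub["solvent"] == s]
                    block = scores.loc[cfeats, sids]
                    hm.loc[c, s] = float(np.nanmean(block.to_numpy()))
            heatmaps[(device, assay)] = hm

    return ScoreReport(scores, per_sample, condition_totals, heatmaps, scope)


def total_score(scores: pd.DataFrame, replicate_groups: dict[str, Sequence[str]]) -> pd.DataFrame:
    """Mean +/- SD of per-sample total scores over explicit replicate groups.

    ``replicate_groups`` maps a condition label to the sample ids of its
    replicates.  Groups of size 1 report sd 0 with ``single_replicate`` set.
    """
    rows = []
    for label, sids in replicate_groups.items():
        sids = list(sids)
        if not sids:
            raise ValidationError(f"replicate group {label!r} is empty")
        totals = scores[sids].sum(axis=0, skipna=True).to_numpy(dtype=float)
        single = len(totals) < 2
        rows.append(
            dict(condition=label, n_replicates=len(totals),
                 mean_score=float(totals.mean()),
                 sd_score=0.0 if single else float(totals.std(ddof=1)),
                 single_replicate=single)
        )
    return pd.DataFrame(rows)
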