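"""Reproducibility and short-term stability quality control.

Reproducibility is profiled as the per-feature coefficient of variation
over extraction replicates, CV% = 100 * SD(n-1) / mean, bucketed into
[0, 10), [10, 30] and (30, inf) percent — features with CV% <= 30 are the
conventional "reproducible" fraction.  A feature needs at least two
detected (positive) replicate values for its CV to be defined; undefined
features are flagged and excluded from the bucket percentages.

Short-term stability compares storage days against the day-0 (immediately
frozen) baseline: per feature, v(d) = 100 * (mean_d - mean_0) / mean_0,
aggregated to compound-class level, with |variation| <= 20% the default
acceptance band for calling a class stable at a given day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import FeatureTable, ValidationError

CONDITION_KEYS = ["device", "solvent", "assay", "day", "extraction_mode"]

#: CV% bucket boundaries: [0,10), [10,30], (30,inf)
BUCKET_LABELS = ("cv_lt_10", "cv_10_to_30", "cv_gt_30")


def cv_percent(replicate_values) -> float:
    """CV% = 100 * sample SD (n-1) / mean of replicate intensities.

    Returns NaN (undefined) when fewer than two values are detected
    (positive) or the mean is not positive.
    """
    v = np.asarray(replicate_values, dtype=float)
    if (v > 0).sum() < 2:
        return math.nan
    m = v.mean()
    if m <= 0:
        return math.nan
    return float(100.0 * v.std(ddof=1) / m)


def _bucket(cv: np.ndarray) -> np.ndarray:
    """Bucket index 0/1/2 per defined CV value."""
    return np.where(cv < 10.0, 0, np.where(cv <= 30.0, 1, 2))


@dataclass
class ReproducibilityProfile:
    """Per-feature CV% and bucket percentages per extraction condition."""

    cv: pd.DataFrame  # features x conditions (MultiIndex columns), NaN = undefined
    buckets: pd.DataFrame  # one row per condition: bucket %s and counts
    condition_keys: list[str]


def reproducibility_profile(table: FeatureTable) -> ReproducibilityProfile:
    """CV% of every feature within each replicate group, with Table-style
    bucket percentages.

    Conditions are the (device, solvent, assay, day, extraction_mode)
    replicate groups of the table; CV% is computed on raw intensities.
    """
    if table.normalized or table.log_transformed:
        raise ValidationError("CV%% is computed on raw intensities")
    table.validate()
    meta = table.samples
    groups = list(meta.groupby(CONDITION_KEYS, sort=False))
    if not groups:
        raise ValidationError("table has no samples")

    cols, cv_cols, rows = [], [], []
    for key_vals, sub in groups:
        X = table.intensities[sub.index].to_numpy()
        detected = (X > 0).sum(axis=1)
        means = X.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = 100.0 * X.std(axis=1, ddof=1) / means
        cv[(detected < 2) | (means <= 0)] = np.nan
        cols.append(key_vals)
        cv_cols.append(cv)

        defined = cv[~np.isnan(cv)]
        n_used = defined.size
        row = dict(zip(CONDITION_KEYS, key_vals))
        row["n_features_used"] = n_used
        row["n_features_undefined"] = int(cv.size - n_used)
        if n_used == 0:
            raise ValidationError(
                f"no feature has a defined CV%% in condition {dict(zip(CONDITION_KEYS, key_vals))}"
            )
        b = _bucket(defined)
        for i, lab in enumerate(BUCKET_LABELS):
            row[lab] = 100.0 * float((b == i).sum()) / n_used
        rows.append(row)

    cv_df = pd.DataFrame(
        np.column_stack(cv_cols),
        index=table.feature_ids,
        columns=pd.MultiIndex.from_tuples(cols, names=CONDITION_KEYS),
    )
    buckets = pd.DataFrame(rows)
    return ReproducibilityProfile(cv_df, buckets, list(CONDITION_KEYS))


@dataclass
class StabilityReport:
    """Class-level % variation to the day-0 baseline and stability calls."""

    variation: pd.DataFrame  # rows: (device, assay, compound_class); columns: day
    stable: pd.DataFrame  # same shape, |variation| <= band
    excluded_features: pd.DataFrame  # per (device, assay, class): n excluded (mean_0 = 0)
    acceptance_band: float
    aggregation: str

    def first_unstable_day(self, device: str, compound_class: str) -> int | None:
        """Earliest storage day at which the class leaves the acceptance
        band, or None if it stays within it over the whole series."""
        row = self.stable.xs(device, level="device").xs(
            compound_class, level="compound_class"
        )
        bad = [d for d in row.columns if not bool(row[d].all())] if isinstance(row, pd.DataFrame) \
            else [d for d, ok in row.items() if not ok]
        return min(bad) if bad else None


def variation_to_baseline(
    table: FeatureTable,
    acceptance_band: float = 20.0,
    aggregation: str = "feature_mean",
) -> StabilityReport:
    """Per-class % variation of signal at each storage day vs day 0.

    Per feature, replicate means are compared to the day-0 replicate mean;
    class variation is the mean of per-feature variations (default), or the
    variation of the class-summed signal with ``aggregation="class_sum"``.
    Features not detected at baseline (day-0 mean of 0) are excluded from
    the class aggregate and counted.  Day-0 variation is identically 0.
    """
    if table.normalized or table.log_transformed:
        raise ValidationError("variation to baseline is computed on raw intensities")
    if aggregation not in ("feature_mean", "class_sum"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    table.validate()
    meta = table.samples
    if (meta["day"] == 0).sum() == 0:
        raise ValidationError("stability table has no day-0 baseline samples")

    days = sorted(meta["day"].unique())
    var_rows, stab_rows, excl_rows, idx = [], [], [], []
    for (device, assay_grp), sub in meta.groupby(["device", "assay"], sort=False):
        if 0 not in set(sub["day"]):
            raise ValidationError(f"device {device!r} has no day-0 samples")
        # per-feature mean per day over replicates
        day_means = {
            d: table.intensities[g.index].mean(axis=1)
            for d, g in sub.groupby("day", sort=True)
        }
        base = day_means[0]
        anno = table.annotations
        feats_assay = anno.index[anno["assay"].isin(
            ["polar", "lipid"] if assay_grp == "both" else [assay_grp]
        )]
        for c, cfeats in anno.loc[feats_assay].groupby("compound_class", sort=False).groups.items():
            b = base.loc[cfeats]
            usable = b.index[b > 0]
            n_excl = len(cfeats) - len(usable)
            row_v, row_s = {}, {}
            for d in days:
                if d not in day_means:
                    row_v[d] = math.nan
                    row_s[d] = True
                    continue
                if len(usable) == 0:
                    row_v[d] = math.nan
                    row_s[d] = False
                    continue
                if d == 0:
                    v = 0.0  # its own baseline, exactly
                elif aggregation == "feature_mean":
                    per_feat = 100.0 * (day_means[d].loc[usable] - b.loc[usable]) / b.loc[usable]
                    v = float(per_feat.mean())
                else:
                    s0, sd_ = b.loc[usable].sum(), day_means[d].loc[usable].sum()
                    v = float(100.0 * (sd_ - s0) / s0)
                row_v[d] = v
                row_s[d] = abs(v) <= acceptance_band if not math.isnan(v) else False
            idx.append((device, assay_grp, c))
            var_rows.append(row_v)
            stab_rows.append(row_s)
            excl_rows.append(dict(n_features=len(cfeats), n_excluded=n_excl))

    index = pd.MultiIndex.from_tuples(idx, names=["device", "assay", "compound_class"])
    variation = pd.DataFrame(var_rows, index=index)[days]
    stable = pd.DataFrame(stab_rows, index=index)[days]
    excluded = pd.DataFrame(excl_rows, index=index)
    return StabilityReport(variation, stable, excluded, acceptance_band, aggregation)


def first_unstable_day_analytic(decay_rate: float, acceptance_band: float = 20.0) -> int | None:
    """Closed-form first day a geometric decay (1-r)^t leaves the band:
    smallest integer t with (1-r)^t - 1 < -band/100."""
    if decay_rate <= 0:
        return None
    frac = 1.0 - acceptance_band / 100.0
    t = math.log(frac) / math.log(1.0 - decay_rate)
    d = math.ceil(t)
    if math.isclose(t, round(t)):
        d = round(t) + 1  # band is inclusive: exactly -band% is still stable
    return int(d)
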