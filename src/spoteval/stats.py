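"""Volcano comparison, PCA overview, and BCA calibration.

* ``volcano`` contrasts two-step (methanol then water) consecutive
  extraction against single extraction: per feature, a two-sided Welch
  t-test on log10 intensities plus a linear fold change of sum-normalized
  group means; joint thresholds p < 0.05 and |FC| >= 1.5 by default, no
  multiple-testing correction unless requested.
* ``pca_overview`` decomposes a normalized, log-transformed table
  (mean-centered per feature; autoscaling optional) and reports the
  variance captured by PC1+PC2, the summary used to judge solvent
  clustering.
* ``bca_fit`` / ``bca_concentration`` calibrate protein concentration from
  562 nm absorbance against the standard series (0-2000 ug/mL) and invert
  the line for unknowns, flagging extrapolation outside the standard range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .io_model import BcaPlate, FeatureTable, ValidationError


class AssayError(ValueError):
    """Calibration data inconsistent with a working assay."""


# --- volcano -----------------------------------------------------------------


@dataclass
class VolcanoResult:
    """Per-feature fold change, p-value and joint significance call."""

    table: pd.DataFrame  # feature_id index: compound_class, log2fc, pvalue, significant
    excluded: list[str]  # features zero in both groups
    p_cut: float
    fc_cut: float
    fdr: bool


def volcano(
    single: FeatureTable,
    consecutive: FeatureTable,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
    fdr: bool = False,
) -> VolcanoResult:
    """Consecutive-vs-single extraction volcano comparison.

    Both tables must be sum-normalized and share the same features.  The
    fold change is the ratio of group means on the linear normalized scale
    (positive direction = higher in the consecutive extraction); p-values
    come from a two-sided Welch t-test on log10 values, zeros replaced by
    half the smallest positive value across both groups.  Features
    undetected in both groups are excluded and listed.
    """
    if not (single.normalized and consecutive.normalized):
        raise ValidationError("volcano requires sum-normalized input tables")
    if single.log_transformed or consecutive.log_transformed:
        raise ValidationError("pass normalized linear-scale tables; logs are taken internally")
    if not single.feature_ids.equals(consecutive.feature_ids):
        raise ValidationError("tables must share the same features in the same order")
    if single.n_samples < 2 or consecutive.n_samples < 2:
        raise ValidationError("each group needs >= 2 replicates")

    A = single.intensities.to_numpy()
    B = consecutive.intensities.to_numpy()
    both_zero = (A.sum(axis=1) == 0) & (B.sum(axis=1) == 0)
    excluded = list(single.feature_ids[both_zero])
    keep = ~both_zero

    mean_a, mean_b = A[keep].mean(axis=1), B[keep].mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_b) - np.log2(mean_a)  # +/-inf when one group is all-zero

    pos = np.concatenate([A[keep][A[keep] > 0], B[keep][B[keep] > 0]])
    floor = pos.min() / 2.0
    la = np.log10(np.where(A[keep] > 0, A[keep], floor))
    lb = np.log10(np.where(B[keep] > 0, B[keep], floor))
    res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0  # zero variance in both groups with equal means

    p_eff = p
    if fdr:
        p_eff = sps.false_discovery_control(p)
    sig = (p_eff < p_cut) & (np.abs(log2fc) >= math.log2(fc_cut))

    out = pd.DataFrame(
        {
            "compound_class": single.annotations.loc[keep, "compound_class"].to_numpy(),
            "log2fc": log2fc,
            "pvalue": p,
            "significant": sig,
        },
        index=single.feature_ids[keep],
    )
    if fdr:
        out.insert(3, "qvalue", p_eff)
    return VolcanoResult(out, excluded, p_cut, fc_cut, fdr)


def split_by_extraction_mode(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Split one table into its single and consecutive extraction samples."""
    meta = table.samples
    single_ids = meta.index[meta["extraction_mode"] == "single"]
    consec_ids = meta.index[meta["extraction_mode"] == "consecutive"]
    if len(single_ids) == 0 or len(consec_ids) == 0:
        raise ValidationError("table lacks one of the extraction modes")
    return table.subset_samples(single_ids), table.subset_samples(consec_ids)


# --- PCA ---------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PCs
    variance_explained_pct: pd.Series  # per PC, sums to 100 over all PCs
    pc12_sum_pct: float


def pca_overview(table: FeatureTable, scale: str = "center") -> PcaResult:
    """PCA of samples; reports the PC1+PC2 variance summary.

    The table should be sum-normalized and log10-transformed first.
    Features are mean-centered; ``scale="autoscale"`` additionally divides
    by the per-feature SD (zero-variance features are dropped).
    """
    if table.n_samples < 2 or table.n_features < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 features")
    if scale not in ("center", "autoscale"):
        raise ValidationError(f"unknown scale {scale!r}")
    X = table.intensities.to_numpy().T  # samples x features
    X = X - X.mean(axis=0)
    if scale == "autoscale":
        sd = X.std(axis=0, ddof=1)
        X = X[:, sd > 0] / sd[sd > 0]
    if not (X != 0).any():
        raise ValidationError("matrix is constant; PCA undefined")

    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pd.Series(
        pca.explained_variance_ratio_ * 100.0,
        index=[f"PC{i + 1}" for i in range(n_comp)],
    )
    score_df = pd.DataFrame(scores, index=table.sample_ids, columns=ratios.index)
    pc12 = float(ratios.iloc[: min(2, n_comp)].sum())
    return PcaResult(score_df, ratios, pc12)


# --- BCA calibration ---------------------------------------------------------


@dataclass
class BcaFit:
    """Linear (or optional quadratic) calibration of absorbance vs
    concentration, with the working range of the standards."""

    coeffs: np.ndarray  # polynomial coefficients, highest power first
    r_squared: float
    working_range: tuple[float, float]
    degree: int

    @property
    def slope(self) -> float:
        return float(self.coeffs[-2])

    @property
    def intercept(self) -> float:
        return float(self.coeffs[-1])


@dataclass
class BcaEstimate:
    sample_id: str | None
    concentration_ug_ml: float
    extrapolated: bool


def bca_fit(standards, degree: int = 1) -> BcaFit:
    """Least-squares calibration curve from the standard series.

    ``standards`` is a BcaPlate, a DataFrame with columns
    ``concentration_ug_ml``/``absorbance``, or a sequence of (conc, abs)
    pairs.  The linear fit must have a positive slope (absorbance grows
    with protein); otherwise the assay failed.
    """
    if isinstance(standards, BcaPlate):
        std = standards.validate().standards
        conc = std["concentration_ug_ml"].to_numpy(dtype=float)
        ab = std["absorbance"].to_numpy(dtype=float)
    elif isinstance(standards, pd.DataFrame):
        conc = standards["concentration_ug_ml"].to_numpy(dtype=float)
        ab = standards["absorbance"].to_numpy(dtype=float)
    else:
        arr = np.asarray(standards, dtype=float)
        conc, ab = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise ValidationError("need >= 2 distinct standard concentrations")
    if degree not in (1, 2):
        raise ValidationError("degree must be 1 or 2")

    coeffs = np.polyfit(conc, ab, deg=degree)
    pred = np.polyval(coeffs, conc)
    ss_res = float(((ab - pred) ** 2).sum())
    ss_tot = float(((ab - ab.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    slope = float(coeffs[-2])
    if slope <= 0:
        raise AssayError(f"non-positive calibration slope ({slope:g}): assay failure")
    return BcaFit(coeffs, r2, (float(conc.min()), float(conc.max())), degree)


def bca_concentration(
    fit: BcaFit, absorbance: float, dilution_factor: float = 1.0, sample_id: str | None = None
) -> BcaEstimate:
    """Invert the calibration curve: concentration = DF * (A - b) / m for
    the linear fit.  Estimates outside the standard range (before applying
    the dilution factor) are flagged as extrapolation."""
    if dilution_factor < 1:
        raise ValidationError("dilution factor must be >= 1")
    if fit.degree == 1:
        raw = (absorbance - fit.intercept) / fit.slope
    else:
        a, b, c = fit.coeffs
        roots = np.roots([a, b, c - absorbance])
        real = roots[np.isreal(roots)].real
        if real.size == 0:
            raise AssayError("absorbance outside the reachable range of the quadratic fit")
        lo, hi = fit.working_range
        raw = float(min(real, key=lambda r: max(lo - r, r - hi, 0.0)))
    lo, hi = fit.working_range
    extrapolated = not (lo <= raw <= hi)
    return BcaEstimate(sample_id, float(dilution_factor * raw), extrapolated)


def bca_apply(fit: BcaFit, plate: BcaPlate) -> pd.DataFrame:
    """Quantify every unknown on the plate."""
    rows = []
    for _, r in plate.validate().unknowns.iterrows():
        est = bca_concentration(fit, float(r["absorbance"]), float(r["dilution_factor"]),
                                sample_id=str(r["sample_id"]))
        rows.append(dict(sample_id=est.sample_id,
                         concentration_ug_ml=est.concentration_ug_ml,
                         extrapolated=est.extrapolated))
    return pd.DataFrame(rows, columns=["sample_id", "concentration_ug_ml", "extrapolated"])
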