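"""Data model and tabular I/O for dried-spot feature tables.

The single currency of the package is the :class:`FeatureTable`: a wide
matrix of LC-MS feature intensities (rows = annotated features, columns =
extracted samples) together with per-feature annotations (assay and
compound class) and per-sample metadata (microsampling device, extraction
solvent, replicate, storage day, extraction mode).

Files are plain text: the intensity matrix as RFC-4180 CSV (or TSV by
extension) whose first column is ``feature_id``, and two TSV side-cars for
sample metadata and feature annotations.  Missing matrix cells are read as
0 and mean "not detected"; there is no separate "not measured" state.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# --- controlled vocabularies -------------------------------------------------

DEVICES = ("Capitainer", "Whatman", "Telimmune")
SOLVENTS = ("CH3OH100", "CH3OH80", "CH3OH50", "ISO", "BuMe")
ASSAYS = ("polar", "lipid")
#: per-sample assay may also be "both": one extract split over both platforms
SAMPLE_ASSAYS = ("polar", "lipid", "both")
EXTRACTION_MODES = ("single", "consecutive")

POLAR_CLASSES = (
    "purine/pyrimidines",
    "carboxylic acids",
    "amino acids",
    "sugars",
    "carnitines",
    "phosphorylated compounds",
)
LIPID_CLASSES = ("Cer", "LPC", "PC", "PE", "PI", "PS", "SM", "TG")
CLASSES_BY_ASSAY = {"polar": POLAR_CLASSES, "lipid": LIPID_CLASSES}
ALL_CLASSES = POLAR_CLASSES + LIPID_CLASSES

#: assay a compound class belongs to
ASSAY_OF_CLASS = {c: a for a, cs in CLASSES_BY_ASSAY.items() for c in cs}

SAMPLE_COLUMNS = ("device", "solvent", "replicate", "day", "assay", "extraction_mode")
ANNOTATION_COLUMNS = ("assay", "compound_class")


class ValidationError(ValueError):
    """A table or file violates the data model."""


def _check_enum(values: pd.Series, allowed: Sequence[str], what: str) -> None:
    bad = sorted(set(values) - set(allowed))
    if bad:
        raise ValidationError(
            f"unknown {what} value(s) {bad}; accepted values: {list(allowed)}"
        )


# --- core container ----------------------------------------------------------


@dataclass
class FeatureTable:
    """Feature intensities plus aligned sample metadata and annotations.

    Attributes
    ----------
    intensities
        Non-negative matrix, index = feature_id, columns = sample_id.
    annotations
        One row per feature (same index order as ``intensities``), columns
        ``assay`` and ``compound_class``.
    samples
        One row per sample (same order as ``intensities`` columns), columns
        ``device, solvent, replicate, day, assay, extraction_mode``.
    normalized, log_transformed
        Processing-state flags set by the preprocessing steps.
    """

    intensities: pd.DataFrame
    annotations: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    log_transformed: bool = False

    # -- basic introspection --

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.annotations.copy(),
            self.samples.copy(),
            self.normalized,
            self.log_transformed,
        )

    def with_intensities(self, values: pd.DataFrame, **flags) -> "FeatureTable":
        out = replace(self, intensities=values)
        for k, v in flags.items():
            setattr(out, k, v)
        return out

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.intensities.columns]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return FeatureTable(
            self.intensities[ids],
            self.annotations,
            self.samples.loc[ids],
            self.normalized,
            self.log_transformed,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.intensities.index]
        if missing:
            raise ValidationError(f"unknown feature id(s): {missing}")
        return FeatureTable(
            self.intensities.loc[ids],
            self.annotations.loc[ids],
            self.samples,
            self.normalized,
            self.log_transformed,
        )

    # -- validation --

    def validate(self) -> "FeatureTable":
        """Raise :class:`ValidationError` on any model violation; return self."""
        X, anno, meta = self.intensities, self.annotations, self.samples

        if X.index.has_duplicates:
            dup = X.index[X.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id(s): {dup}")
        if X.columns.has_duplicates:
            dup = X.columns[X.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        if not X.index.equals(anno.index):
            raise ValidationError("annotation rows do not align with matrix features")
        if not X.columns.equals(pd.Index(meta.index)):
            raise ValidationError("sample metadata rows do not align with matrix columns")
        for col in ANNOTATION_COLUMNS:
            if col not in anno.columns:
                raise ValidationError(f"annotation table missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in meta.columns:
                raise ValidationError(f"sample table missing column {col!r}")

        _check_enum(anno["assay"], ASSAYS, "assay")
        for a in ASSAYS:
            cls = anno.loc[anno["assay"] == a, "compound_class"]
            bad = sorted(set(cls) - set(CLASSES_BY_ASSAY[a]))
            if bad:
                raise ValidationError(
                    f"compound class(es) {bad} not valid for assay {a!r}; "
                    f"accepted values: {list(CLASSES_BY_ASSAY[a])}"
                )
        _check_enum(meta["device"], DEVICES, "device")
        _check_enum(meta["solvent"], SOLVENTS, "solvent")
        _check_enum(meta["assay"], SAMPLE_ASSAYS, "sample assay")
        _check_enum(meta["extraction_mode"], EXTRACTION_MODES, "extraction_mode")
        if (meta["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate must be a positive integer")
        if (meta["day"].astype(int) < 0).any():
            raise ValidationError("storage day must be >= 0")
        key = meta[["device", "solvent", "replicate", "day", "assay", "extraction_mode"]]
        if key.duplicated().any():
            dup = meta.index[key.duplicated()].tolist()
            raise ValidationError(f"duplicate sample design key for sample(s): {dup}")

        vals = X.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("intensity matrix contains non-finite values")
        if not self.log_transformed and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative intensity {vals[i, j]!r} at feature "
                f"{X.index[i]!r}, sample {X.columns[j]!r}"
            )
        return self

    def equals(self, other: "FeatureTable", rtol: float = 1e-9) -> bool:
        return (
            self.normalized == other.normalized
            and self.log_transformed == other.log_transformed
            and self.intensities.index.equals(other.intensities.index)
            and self.intensities.columns.equals(other.intensities.columns)
            and self.annotations.equals(other.annotations)
            and self.samples.equals(other.samples)
            and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=0)
        )


def canonical_sample_order(samples: pd.DataFrame) -> list[str]:
    """Stable sample ordering: device, solvent (solvent in polarity order,
    methanol-rich first), replicate, day, then extraction mode and assay."""
    key = samples.copy()
    key["device"] = pd.Categorical(key["device"], categories=DEVICES, ordered=True)
    key["solvent"] = pd.Categorical(key["solvent"], categories=SOLVENTS, ordered=True)
    key["extraction_mode"] = pd.Categorical(
        key["extraction_mode"], categories=EXTRACTION_MODES, ordered=True
    )
    key["assay"] = pd.Categorical(key["assay"], categories=SAMPLE_ASSAYS, ordered=True)
    order = key.sort_values(
        ["device", "solvent", "replicate", "day", "extraction_mode", "assay"],
        kind="stable",
    ).index
    return list(order)


# --- file I/O ----------------------------------------------------------------

_FLAG_PREFIX = "# spoteval:"


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_feature_table(
    matrix_path: str | Path,
    samples_path: str | Path,
    annotations_path: str | Path,
) -> FeatureTable:
    """Read and validate a feature table from its three text files.

    The matrix file may start with a ``# spoteval:`` comment line carrying
    the processing-state flags written by :func:`write_feature_table`.
    Blank cells are interpreted as "not detected" and mapped to 0.
    """
    matrix_path = Path(matrix_path)
    normalized = log_transformed = False
    with open(matrix_path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith(_FLAG_PREFIX):
            for tok in first[len(_FLAG_PREFIX):].split():
                k, _, v = tok.partition("=")
                if k == "normalized":
                    normalized = v == "true"
                elif k == "log_transformed":
                    log_transformed = v == "true"
            body = fh.read()
        else:
            body = first + fh.read()

    X = pd.read_csv(io.StringIO(body), sep=_sep_for(matrix_path), index_col=0)
    X.index = X.index.astype(str)
    X.columns = X.columns.astype(str)
    X = X.apply(pd.to_numeric).fillna(0.0).astype(float)

    meta = pd.read_csv(samples_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError("sample metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    if "assay" not in meta.columns:
        meta["assay"] = "both"
    for col in ("replicate", "day"):
        meta[col] = pd.to_numeric(meta[col]).astype(int)

    anno = pd.read_csv(annotations_path, sep="\t", dtype=str)
    if "feature_id" not in anno.columns:
        raise ValidationError("feature annotation must have a 'feature_id' column")
    anno = anno.set_index("feature_id")

    extra = [s for s in meta.index if s not in X.columns]
    if extra:
        raise ValidationError(f"sample id(s) {extra} in metadata but not in matrix")
    extra = [s for s in X.columns if s not in meta.index]
    if extra:
        raise ValidationError(f"sample id(s) {extra} in matrix but not in metadata")
    missing = [f for f in X.index if f not in anno.index]
    if missing:
        raise ValidationError(f"feature id(s) {missing} lack annotations")

    table = FeatureTable(
        intensities=X[list(meta.index)],
        annotations=anno.loc[X.index, list(ANNOTATION_COLUMNS)],
        samples=meta[list(SAMPLE_COLUMNS)],
        normalized=normalized,
        log_transformed=log_transformed,
    )
    return table.validate()


def write_feature_table(
    table: FeatureTable,
    matrix_path: str | Path,
    samples_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Write the three text files of a feature table.

    Sample columns are canonicalized (sorted by device, solvent, replicate,
    day) so repeated writes of equivalent tables are byte-identical.
    """
    table.validate()
    order = canonical_sample_order(table.samples)
    X = table.intensities[order]
    meta = table.samples.loc[order]

    matrix_path = Path(matrix_path)
    sep = _sep_for(matrix_path)
    flags = (
        f"{_FLAG_PREFIX} normalized={'true' if table.normalized else 'false'} "
        f"log_transformed={'true' if table.log_transformed else 'false'}\n"
    )
    with open(matrix_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(flags)
        X.to_csv(fh, sep=sep, index_label="feature_id", float_format="%.12g", lineterminator="\n")
    meta.to_csv(samples_path, sep="\t", index_label="sample_id", lineterminator="\n")
    table.annotations.to_csv(
        annotations_path, sep="\t", index_label="feature_id", lineterminator="\n"
    )


# --- BCA plate ---------------------------------------------------------------


@dataclass
class BcaPlate:
    """Absorbance readings of a bicinchoninic-acid protein assay at 562 nm.

    ``standards``: reference points (concentration in ug/mL, absorbance in AU).
    ``unknowns``: samples to quantify, with their dilution factors (>= 1).
    """

    standards: pd.DataFrame  # columns: concentration_ug_ml, absorbance
    unknowns: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "absorbance", "dilution_factor"]
        )
    )

    def validate(self) -> "BcaPlate":
        std = self.standards
        if std["concentration_ug_ml"].nunique() < 2:
            raise ValidationError("BCA calibration needs >= 2 distinct standard concentrations")
        if (std["concentration_ug_ml"] < 0).any():
            raise ValidationError("standard concentrations must be >= 0")
        for df, col in ((std, "absorbance"), (self.unknowns, "absorbance")):
            if len(df) and not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise ValidationError("absorbances must be finite")
        if len(self.unknowns) and (self.unknowns["dilution_factor"] < 1).any():
            raise ValidationError("dilution factors must be >= 1")
        return self


def read_bca_plate(standards_path: str | Path, unknowns_path: str | Path | None = None) -> BcaPlate:
    std = pd.read_csv(standards_path)
    if unknowns_path is not None:
        unk = pd.read_csv(unknowns_path)
        if "dilution_factor" not in unk.columns:
            unk["dilution_factor"] = 1.0
    else:
        unk = pd.DataFrame(columns=["sample_id", "absorbance", "dilution_factor"])
    return BcaPlate(standards=std, unknowns=unk).validate()
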