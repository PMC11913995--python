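"""Synthetic LC-MS feature tables emulating a dried-spot extraction study.

The generator reproduces the statistical structure the downstream analyses
assume, not chromatography: each feature has a latent base abundance (drawn
log-uniformly), each (compound class, solvent, device) combination has a
relative extraction yield in [0, 1], replicate scatter is multiplicative
lognormal noise parameterised by a target CV, signals below an absolute
detection limit are censored to 0, and room-temperature storage degrades
each class geometrically (a constant fractional loss per day).

Three designs are produced, mirroring a device x solvent screen:

* extraction experiment — one sample per (device, solvent, replicate), day 0;
* stability series — one solvent, samples at storage days 0..5;
* consecutive-extraction pair — single vs two-step (methanol then water)
  extraction, n replicates each, with per-class gain factors >= 1.

Every generated table comes with a :class:`SyntheticTruth` recording the
ground truth (base abundances, yields, decay rates, seed) so tests can
check parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ASSAY_OF_CLASS,
    DEVICES,
    LIPID_CLASSES,
    POLAR_CLASSES,
    SOLVENTS,
    FeatureTable,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


# --- default study conditions ------------------------------------------------
#
# Relative yields per (class, solvent); the same profile is used for every
# device.  Polar classes are extracted best by aqueous methanol (the most
# water-rich solvent wins for phosphorylated compounds), poorly by pure
# isopropanol; lipid yields fall with water content, with pure methanol,
# isopropanol and butanol/methanol all effective.  Solvent order:
# CH3OH100, CH3OH80, CH3OH50, ISO, BuMe.

_DEFAULT_YIELD = {
    "purine/pyrimidines":       (0.70, 0.85, 0.95, 0.15, 0.40),
    "carboxylic acids":         (0.70, 0.85, 0.95, 0.15, 0.40),
    "amino acids":              (0.75, 0.90, 0.95, 0.20, 0.45),
    "sugars":                   (0.70, 0.85, 0.90, 0.15, 0.40),
    "carnitines":               (0.80, 0.85, 0.90, 0.30, 0.50),
    "phosphorylated compounds": (0.30, 0.60, 0.95, 0.10, 0.20),
    "Cer": (0.90, 0.50, 0.10, 0.85, 0.85),
    "LPC": (0.85, 0.70, 0.20, 0.70, 0.70),
    "PC":  (0.95, 0.50, 0.10, 0.85, 0.90),
    "PE":  (0.90, 0.50, 0.10, 0.85, 0.85),
    "PI":  (0.85, 0.45, 0.10, 0.80, 0.80),
    "PS":  (0.85, 0.45, 0.10, 0.80, 0.80),
    "SM":  (0.90, 0.50, 0.10, 0.85, 0.85),
    "TG":  (0.95, 0.30, 0.05, 0.90, 0.90),
}

# Per-day fractional loss at room temperature.  Most classes degrade slowly
# (within the +/-20% acceptance band over 5 days); the labile classes
# (nucleobases, sugars, ceramides, PE) lose ~10%/day and cross the band
# between day 2 and day 3.
_DEFAULT_DECAY = {c: 0.03 for c in POLAR_CLASSES + LIPID_CLASSES}
_DEFAULT_DECAY.update({"purine/pyrimidines": 0.10, "sugars": 0.10, "Cer": 0.10, "PE": 0.10})


def default_class_yield(
    classes: Sequence[str] | None = None,
    devices: Sequence[str] = DEVICES,
) -> dict[tuple[str, str, str], float]:
    """Default (class, solvent, device) -> yield map for the 14 study classes."""
    classes = list(classes) if classes is not None else list(_DEFAULT_YIELD)
    out: dict[tuple[str, str, str], float] = {}
    for c in classes:
        for s, y in zip(SOLVENTS, _DEFAULT_YIELD[c]):
            for d in devices:
                out[(c, s, d)] = y
    return out


@dataclass
class SyntheticConfig:
    """Parameters of the generator; defaults emulate the study design
    (3 devices x 5 solvents x 3 replicates, 14 compound classes).

    noise_cv is the target coefficient of variation of replicate scatter;
    the lognormal sigma is derived as sqrt(ln(1 + cv^2)) so the realised CV
    equals the target exactly.  noise_cv = 0 switches noise off (useful for
    analytic limits).  The detection limit is applied after noise.
    """

    n_features_per_class: int = 27
    class_yield: Mapping[tuple[str, str, str], float] = field(default_factory=default_class_yield)
    base_intensity_log10_range: tuple[float, float] = (4.0, 7.0)
    noise_cv: float = 0.15
    detection_limit: float = 2000.0
    decay_rate: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DECAY))
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_features_per_class < 1:
            raise ConfigError("n_features_per_class must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.class_yield:
            raise ConfigError("class_yield map is empty")
        for k, y in self.class_yield.items():
            if not 0.0 <= y <= 1.0:
                raise ConfigError(f"yield {y} for {k} outside [0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        for c, r in self.decay_rate.items():
            if not 0.0 <= r < 1.0:
                raise ConfigError(f"decay rate {r} for {c!r} outside [0, 1)")
        lo, hi = self.base_intensity_log10_range
        if hi < lo:
            raise ConfigError("base_intensity_log10_range must be (low, high)")
        return self

    # derived vocabulary, in canonical order
    @property
    def classes(self) -> list[str]:
        present = {k[0] for k in self.class_yield}
        return [c for c in POLAR_CLASSES + LIPID_CLASSES if c in present]

    @property
    def solvents(self) -> list[str]:
        present = {k[1] for k in self.class_yield}
        return [s for s in SOLVENTS if s in present]

    @property
    def devices(self) -> list[str]:
        present = {k[2] for k in self.class_yield}
        return [d for d in DEVICES if d in present]

    def yield_for(self, compound_class: str, solvent: str, device: str) -> float:
        try:
            return self.class_yield[(compound_class, solvent, device)]
        except KeyError:
            raise ConfigError(
                f"no class_yield configured for ({compound_class!r}, {solvent!r}, {device!r})"
            ) from None

    def decay_for(self, compound_class: str) -> float:
        return float(self.decay_rate.get(compound_class, 0.0))


@dataclass
class SyntheticTruth:
    """Ground truth of one generated table (noise-free expectation level)."""

    base_intensity: pd.Series  # per feature_id
    feature_class: pd.Series  # per feature_id
    class_yield: Mapping[tuple[str, str, str], float]
    decay_rate: Mapping[str, float]
    noise_cv: float
    seed: int

    def expected_intensity(self, device: str, solvent: str, day: int = 0) -> pd.Series:
        """Noise-free signal level per feature for one condition (before
        detection-limit censoring)."""
        y = self.feature_class.map(
            lambda c: self.class_yield[(c, solvent, device)]
        ).astype(float)
        surv = self.feature_class.map(
            lambda c: (1.0 - self.decay_rate.get(c, 0.0)) ** day
        ).astype(float)
        return self.base_intensity * y * surv


# --- generation --------------------------------------------------------------


def _slug(compound_class: str) -> str:
    return compound_class.replace("/", "_").replace(" ", "_")


def _draw_features(config: SyntheticConfig, rng: np.random.Generator):
    """Feature ids, classes and base abundances; consumes the stream first."""
    ids, classes = [], []
    for c in config.classes:
        for i in range(1, config.n_features_per_class + 1):
            ids.append(f"{_slug(c)}_{i:03d}")
            classes.append(c)
    lo, hi = config.base_intensity_log10_range
    base = 10.0 ** rng.uniform(lo, hi, size=len(ids))
    idx = pd.Index(ids, name="feature_id")
    anno = pd.DataFrame(
        {
            "assay": [ASSAY_OF_CLASS[c] for c in classes],
            "compound_class": classes,
        },
        index=idx,
    )
    return anno, pd.Series(base, index=idx), pd.Series(classes, index=idx)


def _noise(config: SyntheticConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if config.noise_cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _censor(config: SyntheticConfig, values: np.ndarray) -> np.ndarray:
    out = values.copy()
    out[out < config.detection_limit] = 0.0
    return out


def _assemble(config, anno, columns, sample_rows) -> FeatureTable:
    X = pd.DataFrame(columns, index=anno.index)
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    return FeatureTable(X, anno, meta).validate()


def generate_extraction_experiment(
    config: SyntheticConfig,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Solvent-screen design: one day-0 sample per (device, solvent, replicate).

    Intensity = base x yield(class, solvent, device) x lognormal noise,
    censored at the detection limit.  Deterministic for a fixed seed; the
    random stream is consumed feature-first, then sample by sample in
    canonical (device, solvent, replicate) order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    anno, base, fclass = _draw_features(config, rng)

    columns: dict[str, np.ndarray] = {}
    rows = []
    for d in config.devices:
        for s in config.solvents:
            level = base.to_numpy() * np.array(
                [config.yield_for(c, s, d) for c in fclass]
            )
            for r in range(1, config.n_replicates + 1):
                sid = f"{d}_{s}_r{r}"
                columns[sid] = _censor(config, level * _noise(config, rng, len(base)))
                rows.append(
                    dict(sample_id=sid, device=d, solvent=s, replicate=r,
                         day=0, assay="both", extraction_mode="single")
                )
    table = _assemble(config, anno, columns, rows)
    truth = SyntheticTruth(base, fclass, dict(config.class_yield),
                           dict(config.decay_rate), config.noise_cv, config.seed)
    return table, truth


def generate_stability_series(
    config: SyntheticConfig,
    days: Sequence[int],
    solvent: str = "CH3OH100",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Room-temperature storage design at one solvent.

    Expected intensity at day t is the day-0 level times (1 - decay_rate)^t
    for the feature's class.  ``days`` must contain 0 (the frozen baseline).
    """
    config.validate()
    days = sorted(int(t) for t in days)
    if 0 not in days:
        raise ConfigError("stability series requires day 0 as baseline")
    if any(t < 0 for t in days):
        raise ConfigError("storage days must be >= 0")
    rng = np.random.default_rng(config.seed)
    anno, base, fclass = _draw_features(config, rng)

    columns: dict[str, np.ndarray] = {}
    rows = []
    for d in config.devices:
        level0 = base.to_numpy() * np.array(
            [config.yield_for(c, solvent, d) for c in fclass]
        )
        surv_rate = np.array([1.0 - config.decay_for(c) for c in fclass])
        for t in days:
            level = level0 * surv_rate**t
            for r in range(1, config.n_replicates + 1):
                sid = f"{d}_{solvent}_d{t}_r{r}"
                columns[sid] = _censor(config, level * _noise(config, rng, len(base)))
                rows.append(
                    dict(sample_id=sid, device=d, solvent=solvent, replicate=r,
                         day=t, assay="both", extraction_mode="single")
                )
    table = _assemble(config, anno, columns, rows)
    truth = SyntheticTruth(base, fclass, dict(config.class_yield),
                           dict(config.decay_rate), config.noise_cv, config.seed)
    return table, truth


def generate_consecutive_pair(
    config: SyntheticConfig,
    boost: Mapping[str, float],
    solvent: str = "CH3OH100",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Paired single vs two-step (methanol then water) extraction design.

    ``boost`` maps compound class -> multiplicative gain (>= 1) of the
    consecutive extraction over the single one; classes not listed gain 1.
    Produces n_replicates samples per mode and device.
    """
    config.validate()
    for c, b in boost.items():
        if b < 1.0:
            raise ConfigError(f"boost {b} for {c!r} < 1; only gains are modelled")
    rng = np.random.default_rng(config.seed)
    anno, base, fclass = _draw_features(config, rng)
    gain = np.array([float(boost.get(c, 1.0)) for c in fclass])

    columns: dict[str, np.ndarray] = {}
    rows = []
    for d in config.devices:
        level = base.to_numpy() * np.array(
            [config.yield_for(c, solvent, d) for c in fclass]
        )
        for mode, mult in (("single", 1.0), ("consecutive", gain)):
            for r in range(1, config.n_replicates + 1):
                sid = f"{d}_{mode}_r{r}"
                columns[sid] = _censor(config, level * mult * _noise(config, rng, len(base)))
                rows.append(
                    dict(sample_id=sid, device=d, solvent=solvent, replicate=r,
                         day=0, assay="both", extraction_mode=mode)
                )
    table = _assemble(config, anno, columns, rows)
    truth = SyntheticTruth(base, fclass, dict(config.class_yield),
                           dict(config.decay_rate), config.noise_cv, config.seed)
    return table, truth


# --- config file support -----------------------------------------------------


def config_from_dict(data: dict) -> SyntheticConfig:
    """Build a config from a plain (YAML/JSON-style) dictionary.

    ``class_yield`` may be nested class -> solvent -> yield (applied to all
    devices listed under ``devices``, default all three) or a flat mapping
    with "class|solvent|device" keys.
    """
    kwargs = dict(data)
    devices = kwargs.pop("devices", list(DEVICES))
    cy = kwargs.pop("class_yield", None)
    if cy is None:
        kwargs["class_yield"] = default_class_yield(devices=devices)
    elif all(isinstance(v, dict) for v in cy.values()):
        flat = {}
        for c, per_solvent in cy.items():
            for s, y in per_solvent.items():
                for d in devices:
                    flat[(c, s, d)] = float(y)
        kwargs["class_yield"] = flat
    else:
        kwargs["class_yield"] = {tuple(k.split("|")): float(v) for k, v in cy.items()}
    if "base_intensity_log10_range" in kwargs:
        kwargs["base_intensity_log10_range"] = tuple(kwargs["base_intensity_log10_range"])
    return SyntheticConfig(**kwargs).validate()
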