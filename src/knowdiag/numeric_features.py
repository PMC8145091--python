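"""Numeric clinical indicators: unit normalization, plausibility validation,
imputation and z-scoring.

Clinical records mix units ("menopause 8 weeks" vs "menopause 2 months") and
contain transcription errors (a uterine height of "29 m").  Each feature in
the schema carries a target unit, an inclusive plausibility range and a table
of multiplicative unit conversions; values outside the range are treated as
missing — deleted rather than clamped — and imputed from the training mean so
every record still yields a fixed-length vector for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .corpus_io import Record

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "NumericVector",
    "NumericExtractor",
    "normalize_unit",
    "validate",
    "parse_raw",
    "extract_vector",
    "load_schema",
    "save_schema",
]


@dataclass
class FeatureSpec:
    """One physiological index: target unit, inclusive range, conversions."""

    name: str
    unit: str
    min: float
    max: float
    conversions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.min < self.max:
            raise ValueError(f"feature {self.name!r}: min must be < max")
        for u, f in self.conversions.items():
            if f <= 0:
                raise ValueError(f"feature {self.name!r}: factor for {u!r} must be > 0")


class FeatureSchema:
    """Ordered feature list; the order defines the layout of the vector n."""

    def __init__(self, features: Sequence[FeatureSpec]):
        self.features = list(features)
        self.index = {f.name: i for i, f in enumerate(self.features)}

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        return self.features[self.index[name]]


@dataclass
class NumericVector:
    """Fixed-length numeric vector with per-feature validity flags."""

    values: np.ndarray
    valid: np.ndarray  # True where the raw value was present and plausible


def normalize_unit(value: float, source_unit: str, spec: FeatureSpec) -> float:
    """Convert a value from ``source_unit`` into the feature's target unit."""
    if source_unit == spec.unit:
        return float(value)
    if source_unit not in spec.conversions:
        raise ValueError(
            f"feature {spec.name!r}: no conversion from unit {source_unit!r}"
        )
    return float(value) * spec.conversions[source_unit]


def validate(value: float, spec: FeatureSpec) -> bool:
    """Plausibility check against the inclusive [min, max] range."""
    return spec.min <= value <= spec.max


def parse_raw(raw: str, spec: FeatureSpec) -> float | None:
    """Parse a raw field like ``"29"`` or ``"8 weeks"`` into the target unit.

    Returns None for empty/unparseable values (treated as missing); raises on
    a recognized number with an unknown unit.
    """
    parts = raw.strip().split()
    if not parts:
        return None
    try:
        value = float(parts[0])
    except ValueError:
        return None
    unit = parts[1] if len(parts) > 1 else spec.unit
    return normalize_unit(value, unit, spec)


def extract_vector(
    record: Record,
    schema: FeatureSchema,
    impute: Sequence[float] | None = None,
) -> NumericVector:
    """Extract the record's numeric vector n with validity flags.

    Missing and out-of-range values are imputed from ``impute`` (one value per
    feature; zeros when not given) and flagged invalid.
    """
    if len(schema) == 0:
        raise ValueError("schema must be non-empty")
    fill = np.zeros(len(schema)) if impute is None else np.asarray(impute, dtype=float)
    values = fill.copy()
    valid = np.zeros(len(schema), dtype=bool)
    for i, spec in enumerate(schema):
        raw = record.numeric_raw.get(spec.name)
        if raw is None:
            continue
        parsed = parse_raw(raw, spec)
        if parsed is None or not validate(parsed, spec):
            continue  # error data are deleted, not clamped
        values[i] = parsed
        valid[i] = True
    return NumericVector(values=values, valid=valid)


class NumericExtractor:
    """Fit imputation means and z-score scaling on training records only."""

    def __init__(self, schema: FeatureSchema):
        self.schema = schema
        self.means_: np.ndarray | None = None
        self.mu_: np.ndarray | None = None
        self.sigma_: np.ndarray | None = None

    def fit(self, records: Iterable[Record]) -> "NumericExtractor":
        records = list(records)
        raw = np.full((len(records), len(self.schema)), np.nan)
        for r, rec in enumerate(records):
            nv = extract_vector(rec, self.schema)
            raw[r, nv.valid] = nv.values[nv.valid]
        # statistics over valid values only: imputed slots then standardize
        # to exactly 0 and valid values to mean 0 / unit variance
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN feature
            self.means_ = np.nan_to_num(np.nanmean(raw, axis=0), nan=0.0)
            sigma = np.nan_to_num(np.nanstd(raw, axis=0), nan=1.0)
        self.mu_ = self.means_.copy()
        self.sigma_ = np.where(sigma > 0, sigma, 1.0)
        return self

    def transform(self, records: Iterable[Record]) -> tuple[np.ndarray, np.ndarray]:
        """Z-scored numeric matrix + validity mask, using training statistics."""
        if self.means_ is None:
            raise RuntimeError("NumericExtractor must be fitted first")
        records = list(records)
        out = np.zeros((len(records), len(self.schema)))
        valid = np.zeros_like(out, dtype=bool)
        for r, rec in enumerate(records):
            nv = extract_vector(rec, self.schema, impute=self.means_)
            out[r] = (nv.values - self.mu_) / self.sigma_
            valid[r] = nv.valid
        return out, valid

    def fit_transform(self, records: Iterable[Record]) -> tuple[np.ndarray, np.ndarray]:
        records = list(records)
        return self.fit(records).transform(records)


def load_schema(path: str | Path) -> FeatureSchema:
    """Load a feature schema from a YAML/JSON config file."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    specs = [
        FeatureSpec(
            name=item["name"],
            unit=item["unit"],
            min=float(item["min"]),
            max=float(item["max"]),
            conversions={k: float(v) for k, v in item.get("conversions", {}).items()},
        )
        for item in data["features"]
    ]
    return FeatureSchema(specs)


def save_schema(schema: FeatureSchema, path: str | Path) -> None:
    data = {
        "features": [
            {
                "name": f.name,
                "unit": f.unit,
                "min": f.min,
                "max": f.max,
                "conversions": f.conversions,
            }
            for f in schema
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
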