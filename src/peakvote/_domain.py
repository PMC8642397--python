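"""Shared domain containers for chromatographic peak data.

The objects here mirror what a Skyline chromatogram/precursor export carries:
per-isotope extracted-ion-chromatogram (XIC) traces with integration
boundaries, grouped per precursor, plus the nine-feature vector the
classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "IsotopeTrace",
    "PrecursorPeakGroup",
    "PeakFeatures",
    "AnnotatedExample",
]

#: Canonical feature order used everywhere (tables, matrices, persisted models).
FEATURE_NAMES: tuple[str, ...] = (
    "idotp",
    "avg_mass_error_ppm",
    "snr",
    "jagging",
    "fwhm_sd",
    "shape_similarity",
    "boundary_intensity",
    "coelution_score",
    "coelution_count",
)

LABEL_TYPES = ("light", "heavy", "none")


@dataclass
class IsotopeTrace:
    """One isotope's chromatogram: intensity vs retention time plus the
    integration boundaries Skyline assigned to the peak.

    Parameters
    ----------
    isotope_index
        0, 1 or 2 for the monoisotopic (M), M+1 and M+2 traces.
    times
        Retention times in minutes, strictly increasing.
    intensities
        Non-negative intensities (arbitrary units), same length as ``times``.
    boundary_start, boundary_end
        Integration interval in minutes. Clamped into the sampled time range.
    boundary_defaulted
        True when no boundaries were supplied and the full trace extent was
        used instead (audit flag).
    """

    isotope_index: int
    times: np.ndarray
    intensities: np.ndarray
    boundary_start: float
    boundary_end: float
    boundary_defaulted: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.isotope_index not in (0, 1, 2):
            raise ValueError(f"isotope_index must be 0, 1 or 2, got {self.isotope_index}")
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D series")
        if self.times.shape != self.intensities.shape:
            raise ValueError(
                f"times ({self.times.size}) and intensities ({self.intensities.size}) "
                "must have the same length"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        lo, hi = float(self.times[0]), float(self.times[-1])
        self.boundary_start = float(min(max(self.boundary_start, lo), hi))
        self.boundary_end = float(min(max(self.boundary_end, lo), hi))
        if self.boundary_start > self.boundary_end:
            raise ValueError("boundary_start must be <= boundary_end")

    def window(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and intensities of the samples inside the integration interval."""
        mask = (self.times >= self.boundary_start) & (self.times <= self.boundary_end)
        return self.times[mask], self.intensities[mask]


@dataclass
class PrecursorPeakGroup:
    """A precursor's set of isotope traces with its report-level metadata.

    ``mass_error_ppm`` may be a single signed value for the precursor or a
    per-isotope mapping; ``areas`` maps isotope index to the integrated XIC
    area when the report provides one.
    """

    modified_sequence: str
    charge: int
    label_type: str = "none"
    traces: list[IsotopeTrace] = field(default_factory=list)
    idotp: Optional[float] = None
    mass_error_ppm: Optional[float | dict[int, float]] = None
    areas: dict[int, float] = field(default_factory=dict)
    replicate: Optional[str] = None
    retention_time: Optional[float] = None  # metadata only, not a feature

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.label_type not in LABEL_TYPES:
            raise ValueError(f"label_type must be one of {LABEL_TYPES}, got {self.label_type!r}")
        seen = [t.isotope_index for t in self.traces]
        if len(seen) != len(set(seen)):
            raise ValueError(f"duplicate isotope_index among traces: {sorted(seen)}")
        if self.idotp is not None and not (0.0 <= self.idotp <= 1.0):
            raise ValueError(f"idotp must lie in [0, 1], got {self.idotp}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.modified_sequence, self.charge, self.label_type)

    def trace(self, isotope_index: int) -> Optional[IsotopeTrace]:
        for t in self.traces:
            if t.isotope_index == isotope_index:
                return t
        return None

    def total_area(self) -> float:
        """Sum of the M, M+1 and M+2 XIC areas; a missing isotope contributes 0."""
        return float(sum(self.areas.get(i, 0.0) for i in (0, 1, 2)))


@dataclass(frozen=True)
class PeakFeatures:
    """The nine-feature vector describing one chromatographic peak group.

    All fields are finite; upstream values that could not be computed are 0
    by convention so every peak yields a usable vector.
    """

    idotp: float = 0.0
    avg_mass_error_ppm: float = 0.0
    snr: float = 0.0
    jagging: float = 0.0
    fwhm_sd: float = 0.0
    shape_similarity: float = 0.0
    boundary_intensity: float = 0.0
    coelution_score: float = 0.0
    coelution_count: float = 0.0

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"feature {name} is not finite: {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PeakFeatures":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got shape {values.shape}"
            )
        return cls(**dict(zip(FEATURE_NAMES, values.tolist())))


@dataclass
class AnnotatedExample:
    """A feature vector with its manual peptide/noise annotation."""

    features: PeakFeatures
    annotation: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.annotation not in ("peptide", "noise"):
            raise ValueError(
                f"annotation must be 'peptide' or 'noise', got {self.annotation!r}"
            )


def feature_matrix(examples: Sequence[AnnotatedExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into an (n, 9) matrix and a label vector ('peptide'/'noise')."""
    X = np.vstack([ex.features.to_array() for ex in examples])
    y = np.array([ex.annotation for ex in examples])
    return X, y
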