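"""Core domain types shared across the pipeline.

The unit of ingestion is a :class:`SlideRaster` (an RGB pixel grid with a
physical scale), which is tessellated into :class:`Tile` objects, scored to
:class:`TileScore`, and collapsed to one :class:`PatientScore` per patient.
Decision rules are :class:`ThresholdPolicy` objects and their evaluation
produces :class:`ConfusionStats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SlideRaster",
    "Tile",
    "QCRecord",
    "StainContext",
    "TileScore",
    "PatientScore",
    "ThresholdPolicy",
    "ConfusionStats",
    "MetricCI",
    "Cohort",
    "PatientRecord",
    "DegenerateStainError",
    "UndefinedMetricError",
    "CalibrationError",
]


class DegenerateStainError(ValueError):
    """Raised when a stain matrix cannot be estimated (blank or single-dye image)."""


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined on its input (e.g. AUROC on one class)."""


class CalibrationError(ValueError):
    """Raised when a threshold cannot be calibrated (e.g. no positive patients)."""


@dataclass
class SlideRaster:
    """An RGB slide raster with physical scale metadata.

    Parameters
    ----------
    pixels
        ``H x W x 3`` unsigned 8-bit RGB array.
    microns_per_pixel
        Physical edge length of one pixel in micrometers; must be finite
        and positive.
    slide_id, patient_id
        Identifiers carried through tiling and scoring.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    slide_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"slide pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide must have H, W >= 1")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"slide pixels must be uint8, got {self.pixels.dtype}")
        mpp = self.microns_per_pixel
        if mpp is None or not math.isfinite(mpp) or mpp <= 0:
            raise ValueError(f"microns_per_pixel must be finite and positive, got {mpp!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class Tile:
    """A square sub-image cut from a slide.

    ``origin_x``/``origin_y`` are 0-based pixel offsets in the source slide
    (x = column, y = row); the tile's footprint in the source is the half-open
    square ``[x, x + src_edge_px) x [y, y + src_edge_px)``. ``pixels`` holds
    the footprint resampled to the configured output edge length.
    """

    pixels: np.ndarray
    origin_x: int
    origin_y: int
    src_edge_px: int
    edge_um: float
    slide_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be ExEx3")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("tile pixels must be square")

    @property
    def out_edge_px(self) -> int:
        return self.pixels.shape[0]


@dataclass
class QCRecord:
    """Quality-control verdict for one tile (edge-quantity blur/background test)."""

    tile: Tile
    edge_score: float
    passed: bool


@dataclass
class StainContext:
    """Macenko stain model of an image.

    ``stain_matrix`` is 3x2: columns are the hematoxylin and eosin
    optical-density vectors (unit Euclidean norm, nonnegative components,
    hematoxylin first). ``max_concentrations`` holds the robust
    (99th-percentile) per-stain concentration scale used for normalization.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2 (columns = H, E)")
        if np.any(self.stain_matrix < -1e-9):
            raise ValueError("stain OD components must be nonnegative")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain columns must have unit Euclidean norm")
        if self.max_concentrations.shape != (2,):
            raise ValueError("max_concentrations must be a 2-vector")


@dataclass
class TileScore:
    """Tile-level MSI probability."""

    tile: Tile
    p_msi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_msi <= 1.0:
            raise ValueError(f"p_msi must be in [0, 1], got {self.p_msi}")


@dataclass
class PatientScore:
    """Patient-level MSI score: the fraction of the patient's tiles called MSI.

    ``label`` is 1 for MSI/dMMR, 0 for MSS/pMMR, None when unknown.
    """

    patient_id: str
    score: float
    n_tiles: int
    cohort_id: str = ""
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")


@dataclass
class ThresholdPolicy:
    """A calibrated decision rule: predict MSI iff patient score >= value."""

    kind: str  # one of {"cohort_specific", "fixed", "learned"}
    value: float
    target_sensitivity: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("cohort_specific", "fixed", "learned"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"policy value must be in [0, 1], got {self.value}")

    def predict(self, scores: Sequence[float]) -> np.ndarray:
        """Binary MSI predictions (1 = MSI) for an array of patient scores."""
        return (np.asarray(scores, dtype=float) >= self.value).astype(int)


@dataclass
class ConfusionStats:
    """Confusion counts plus the derived triage metrics.

    ``ruleout_fraction`` (true negatives over all patients) is the share of
    patients the pre-screen safely excludes from confirmatory molecular
    testing; ``fn_fraction`` (false negatives over all patients) is the share
    of MSI patients it would miss.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else float("nan")

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n if self.n else float("nan")

    @property
    def ruleout_fraction(self) -> float:
        return self.tn / self.n if self.n else float("nan")

    @property
    def fn_fraction(self) -> float:
        return self.fn / self.n if self.n else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "ruleout_fraction": self.ruleout_fraction,
            "fn_fraction": self.fn_fraction,
        }


@dataclass
class MetricCI:
    """Bootstrap percentile confidence interval for a metric."""

    point: float
    lower: float
    upper: float
    n_boot: int
    level: float
    seed: Optional[int] = None
    n_redrawn: int = 0


@dataclass
class PatientRecord:
    """One patient in a manifest: identifier, slide paths (or in-memory slides) and label."""

    patient_id: str
    cohort_id: str
    label: Optional[int]
    slide_paths: list = field(default_factory=list)
    slides: list = field(default_factory=list)  # optional in-memory SlideRasters


@dataclass
class Cohort:
    """A named group of patients evaluated together (one clinical center/study)."""

    cohort_id: str
    patients: list  # list[PatientRecord]

    @property
    def prevalence(self) -> float:
        labels = [p.label for p in self.patients if p.label is not None]
        return float(np.mean(labels)) if labels else float("nan")

    def __len__(self) -> int:
        return len(self.patients)
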