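"""Synthetic slides, tiles and score cohorts with controlled structure.

Two families of generators make every pipeline stage testable without any
slide archive:

* **Texture slides** — two H&E-like tissue classes rendered through the
  Beer-Lambert stain model: the MSI-associated class is a field of dense
  small filled discs (a lymphocyte-rich pattern), the MSS-associated class
  ring/gland-like structures with unstained lumina. Both share an
  eosin-stained stroma background, so only the hematoxylin texture carries
  the class signal. The primitives are deliberately simple: they provide a
  learnable class signal, not histological realism.

* **Score cohorts** — patient-level MSI scores drawn from class-conditional
  Beta distributions with configurable prevalence (default 12%, the
  approximate fraction of sporadic MSI/dMMR colorectal cancers). Scores
  are quantized to tile-count fractions, as real aggregated scores are.
  The generating model's true AUROC, P(X1 > X0), is available in closed
  form for use as an oracle.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, ndimage, stats

from .stain import od_to_rgb
from .types import PatientScore, SlideRaster

__all__ = [
    "TextureSpec",
    "CohortSpec",
    "HE_STAIN_MATRIX",
    "make_synthetic_slide",
    "make_synthetic_cohort",
    "make_synthetic_study",
    "inject_artifacts",
    "beta_auroc",
]

# Classic H&E optical-density vectors (hematoxylin, eosin), unit norm.
HE_STAIN_MATRIX = np.array(
    [
        [0.650, 0.072],
        [0.704, 0.990],
        [0.286, 0.105],
    ]
)
HE_STAIN_MATRIX /= np.linalg.norm(HE_STAIN_MATRIX, axis=0, keepdims=True)


@dataclass
class TextureSpec:
    """Parameters of one tissue-texture class.

    ``primitive`` is ``"discs"`` (filled circles, the MSI-like class) or
    ``"rings"`` (annuli with unstained lumina, the MSS-like class);
    ``density`` is primitives per 256x256 px region; radii are drawn
    uniformly from ``radius_range`` (px).
    """

    label: int
    primitive: str = "discs"
    density: float = 60.0
    radius_range: tuple[float, float] = (3.0, 6.0)
    ring_thickness: float = 4.0
    stain_matrix: np.ndarray = field(default_factory=lambda: HE_STAIN_MATRIX.copy())
    hema_concentration: tuple[float, float] = (0.8, 1.2)
    eosin_concentration: tuple[float, float] = (0.15, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primitive not in ("discs", "rings"):
            raise ValueError(f"unknown primitive {self.primitive!r}")
        if self.density < 0:
            raise ValueError("density must be >= 0")


@dataclass
class CohortSpec:
    """Parameters of one synthetic patient-score cohort."""

    n_patients: int = 200
    prevalence: float = 0.12
    beta_pos: tuple[float, float] = (8.0, 2.0)
    beta_neg: tuple[float, float] = (2.0, 8.0)
    tiles_per_patient: tuple[int, int] = (120, 500)
    cohort_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if min(*self.beta_pos, *self.beta_neg) <= 0:
            raise ValueError("Beta parameters must be positive")


def make_synthetic_slide(
    spec: TextureSpec,
    size_px: int = 768,
    microns_per_pixel: float = 1.0,
    slide_id: str = "synthetic",
    patient_id: str = "",
    seed: Optional[int] = None,
) -> SlideRaster:
    """Render a synthetic H&E-like slide of one texture class.

    Primitives are drawn as hematoxylin concentration fields, an
    eosin-stained stroma is added as smoothed noise, and the two
    concentration channels are composed to RGB via the Beer-Lambert model
    with the spec's stain vectors. Zero density yields a blank
    (background-only) slide whose tiles all fail QC.
    """
    if size_px < 1:
        raise ValueError("size_px must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    hema = np.zeros((size_px, size_px))
    n_prims = rng.poisson(spec.density * (size_px / 256.0) ** 2)
    for _ in range(n_prims):
        cx, cy = rng.uniform(0, size_px, size=2)
        r = rng.uniform(*spec.radius_range)
        conc = rng.uniform(*spec.hema_concentration)
        # Rasterize inside the primitive's bounding box only.
        x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, size_px)
        y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, size_px)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        if spec.primitive == "discs":
            mask = d2 <= r**2
        else:
            inner = max(r - spec.ring_thickness, 0.0)
            mask = (d2 <= r**2) & (d2 >= inner**2)
        region = hema[y0:y1, x0:x1]
        region[mask] = np.maximum(region[mask], conc)
    if spec.density > 0:
        lo, hi = spec.eosin_concentration
        noise = rng.standard_normal((size_px, size_px))
        noise = ndimage.gaussian_filter(noise, sigma=8.0)
        noise = (noise - noise.min()) / max(noise.max() - noise.min(), 1e-12)
        eosin = lo + (hi - lo) * noise
    else:
        eosin = np.zeros((size_px, size_px))
    conc_stack = np.stack([hema.ravel(), eosin.ravel()])  # 2 x Npix
    od = (spec.stain_matrix @ conc_stack).T.reshape(size_px, size_px, 3)
    return SlideRaster(
        pixels=od_to_rgb(od),
        microns_per_pixel=microns_per_pixel,
        slide_id=slide_id,
        patient_id=patient_id,
    )


def make_synthetic_cohort(spec: CohortSpec) -> list[PatientScore]:
    """Draw a labeled patient-score cohort from the class-conditional model.

    Labels are Bernoulli(prevalence); scores are Beta draws quantized to
    the patient's tile count (a score is a fraction of tiles, so
    ``score * n_tiles`` is an integer).
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_patients) < spec.prevalence).astype(int)
    a1, b1 = spec.beta_pos
    a0, b0 = spec.beta_neg
    raw = np.where(
        labels == 1, rng.beta(a1, b1, spec.n_patients), rng.beta(a0, b0, spec.n_patients)
    )
    lo, hi = spec.tiles_per_patient
    n_tiles = rng.integers(lo, hi + 1, size=spec.n_patients)
    scores = np.round(raw * n_tiles) / n_tiles
    return [
        PatientScore(
            patient_id=f"{spec.cohort_id}_p{i:05d}",
            score=float(scores[i]),
            n_tiles=int(n_tiles[i]),
            cohort_id=spec.cohort_id,
            label=int(labels[i]),
        )
    for i in range(spec.n_patients)]


def beta_auroc(
    beta_pos: tuple[float, float], beta_neg: tuple[float, float]
) -> float:
    """Closed-form true AUROC of the generating model: P(X1 > X0).

    Computed as the integral of ``pdf_pos(x) * cdf_neg(x)`` over [0, 1]
    by adaptive quadrature.
    """
    a1, b1 = beta_pos
    a0, b0 = beta_neg
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a0, b0), 0.0, 1.0
    )
    return float(val)


def inject_artifacts(
    slide: SlideRaster, kind: str, severity: float, seed: int = 0
) -> SlideRaster:
    """Degrade a slide with a scanning/preparation artifact.

    ``blur`` applies Gaussian smoothing (sigma = 4 * severity px);
    ``fold`` duplicates a darkened horizontal tissue band (a tissue fold);
    ``overstain`` scales all optical densities by (1 + severity).
    ``severity`` 0 is the identity for every kind. Deterministic per seed.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    px = slide.pixels
    if severity == 0:
        out = px.copy()
    elif kind == "blur":
        out = ndimage.gaussian_filter(
            px.astype(float), sigma=(4.0 * severity, 4.0 * severity, 0.0)
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    elif kind == "fold":
        rng = np.random.default_rng(seed)
        H = px.shape[0]
        band = max(1, int(round(H * min(0.25 * severity, 0.45))))
        src = int(rng.integers(0, H - band + 1))
        dst = int(rng.integers(0, H - band + 1))
        out = px.copy()
        dark = np.clip(px[src : src + band].astype(float) * 0.5, 0, 255)
        out[dst : dst + band] = np.minimum(out[dst : dst + band], dark).astype(np.uint8)
    elif kind == "overstain":
        od = -np.log10((px.astype(float) + 1.0) / 256.0)
        out = od_to_rgb(od * (1.0 + severity))
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return SlideRaster(
        pixels=out,
        microns_per_pixel=slide.microns_per_pixel,
        slide_id=slide.slide_id,
        patient_id=slide.patient_id,
    )


def make_synthetic_study(
    n_cohorts: int = 4,
    patients_per_cohort: int = 8,
    prevalence: float = 0.5,
    slide_px: int = 768,
    microns_per_pixel: float = 1.0,
    seed: int = 0,
) -> list:
    """A miniature multi-cohort imaging study with texture-class slides.

    Each patient has one synthetic slide whose texture class equals their
    MSI label (discs for MSI, rings for MSS); cohorts differ only by seed.
    Prevalence defaults to 0.5 here (not the clinical 12%) so that each
    mini-cohort is guaranteed both classes at desk scale. Returns a list
    of :class:`~msiprescreen.types.Cohort` with in-memory slides.
    """
    from .types import Cohort, PatientRecord

    rng = np.random.default_rng(seed)
    cohorts = []
    for c in range(n_cohorts):
        patients = []
        # Deterministic half/half label layout guarantees both classes.
        labels = (np.arange(patients_per_cohort) % 2 == 0).astype(int)
        if prevalence != 0.5:
            labels = (rng.random(patients_per_cohort) < prevalence).astype(int)
        for i, label in enumerate(labels):
            pid = f"c{c}_p{i:03d}"
            if label == 1:
                spec = TextureSpec(label=1, primitive="discs", radius_range=(3.0, 6.0))
            else:
                spec = TextureSpec(
                    label=0,
                    primitive="rings",
                    radius_range=(8.0, 14.0),
                    density=25.0,
                )
            slide = make_synthetic_slide(
                spec,
                size_px=slide_px,
                microns_per_pixel=microns_per_pixel,
                slide_id=f"{pid}_s0",
                patient_id=pid,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    cohort_id=f"cohort{c}",
                    label=int(label),
                    slides=[slide],
                )
            )
        cohorts.append(Cohort(cohort_id=f"cohort{c}", patients=patients))
    return cohorts
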