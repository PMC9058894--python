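"""Manifest and slide I/O, run configuration, and result writers.

Manifests are CSV/TSV tables with one row per (patient, slide):
``patient_id, cohort_id, label, slide_path`` (and optionally
``microns_per_pixel``, which overrides any resolution metadata embedded in
the image). Labels are encoded 1 = MSI/dMMR, 0 = MSS/pMMR; MSI and dMMR
are treated as interchangeable. Rows with a missing label or missing
image are excluded and counted in a consort-style exclusion report.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .types import Cohort, PatientRecord, SlideRaster

__all__ = [
    "read_manifest",
    "load_slide",
    "write_results",
    "write_patient_scores",
    "read_patient_scores",
    "policy_to_yaml",
    "RunConfig",
    "ManifestError",
]

_LABEL_MAP = {
    "1": 1, "msi": 1, "dmmr": 1, "msi-h": 1,
    "0": 0, "mss": 0, "pmmr": 0, "msi-l": 0,
}
REQUIRED_COLUMNS = ("patient_id", "cohort_id", "label", "slide_path")


class ManifestError(ValueError):
    """Schema or consistency error in a patient manifest."""


def _parse_label(raw) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text in ("", "nan", "na"):
        return None
    if text in _LABEL_MAP:
        return _LABEL_MAP[text]
    try:
        return _LABEL_MAP[str(int(float(text)))]
    except (ValueError, KeyError):
        raise ManifestError(f"unparseable label {raw!r}")


def read_manifest(
    path: str | Path, check_files: bool = False
) -> tuple[list[Cohort], dict]:
    """Assemble cohorts from a manifest table.

    Returns the cohorts plus an exclusion report counting rows dropped for
    a missing label or missing image. Duplicate patient ids across
    cohorts are a hard error (patient ids must be globally unique).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ManifestError(f"manifest missing required column(s): {missing_cols}")

    exclusions = {"missing_label": 0, "missing_image": 0}
    patients: dict[str, PatientRecord] = {}
    for _, row in df.iterrows():
        label = _parse_label(row["label"])
        if label is None:
            exclusions["missing_label"] += 1
            continue
        slide_path = row["slide_path"]
        if (
            not isinstance(slide_path, str)
            or not slide_path.strip()
            or (check_files and not Path(slide_path).exists())
        ):
            exclusions["missing_image"] += 1
            continue
        pid, cid = str(row["patient_id"]), str(row["cohort_id"])
        mpp = None
        if "microns_per_pixel" in df.columns and pd.notna(row["microns_per_pixel"]):
            mpp = float(row["microns_per_pixel"])
        rec = patients.get(pid)
        if rec is None:
            rec = PatientRecord(patient_id=pid, cohort_id=cid, label=label)
            rec.manifest_mpp = mpp  # type: ignore[attr-defined]
            patients[pid] = rec
        elif rec.cohort_id != cid:
            raise ManifestError(
                f"patient {pid!r} appears in cohorts {rec.cohort_id!r} and {cid!r}"
            )
        elif rec.label != label:
            raise ManifestError(f"patient {pid!r} has conflicting labels")
        rec.slide_paths.append(slide_path.strip())

    cohorts: dict[str, Cohort] = {}
    for rec in patients.values():
        cohorts.setdefault(rec.cohort_id, Cohort(cohort_id=rec.cohort_id, patients=[]))
        cohorts[rec.cohort_id].patients.append(rec)
    report = {
        "rows_in": int(len(df)),
        "patients_kept": len(patients),
        **exclusions,
    }
    return list(cohorts.values()), report


def _mpp_from_tiff(path: Path) -> Optional[float]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        xres = tags.get("XResolution")
        unit = tags.get("ResolutionUnit")
        if xres is None or unit is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        px_per_unit = num / den
        unit_um = {2: 25_400.0, 3: 10_000.0}.get(getattr(unit.value, "value", unit.value))
        if unit_um is None:
            return None
        return unit_um / px_per_unit


def load_slide(
    path: str | Path,
    microns_per_pixel: Optional[float] = None,
    slide_id: Optional[str] = None,
    patient_id: str = "",
) -> SlideRaster:
    """Read an RGB TIFF/PNG slide raster.

    The physical scale comes from an explicit ``microns_per_pixel``
    argument (e.g. a manifest column, which always wins) or, for TIFF,
    from the resolution tags. A slide without any scale metadata is a
    metadata error.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        if microns_per_pixel is None:
            microns_per_pixel = _mpp_from_tiff(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    if microns_per_pixel is None:
        raise ValueError(
            f"slide {path.name}: no microns-per-pixel metadata; supply it via "
            "the manifest's microns_per_pixel column"
        )
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    return SlideRaster(
        pixels=np.ascontiguousarray(pixels, dtype=np.uint8),
        microns_per_pixel=float(microns_per_pixel),
        slide_id=slide_id or path.stem,
        patient_id=patient_id,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """YAML-serializable run configuration shared by CLI stages."""

    tile_edge_um: float = 256.0
    out_edge_px: int = 512
    qc_threshold: float = 4.0
    normalize: bool = True
    target_image: Optional[str] = None
    tile_cap: int = 500
    tile_threshold: float = 0.5
    backbone: str = "small_cnn"
    scorer: dict = field(default_factory=dict)
    target_sensitivity: float = 0.95
    fixed_thresholds: tuple = (0.25, 0.50, 0.75)
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fixed_thresholds" in data:
            data["fixed_thresholds"] = tuple(data["fixed_thresholds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fixed_thresholds"] = list(self.fixed_thresholds)
        _atomic_write(path, yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        data = asdict(self)
        data["fixed_thresholds"] = list(self.fixed_thresholds)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_patient_scores(scores, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "cohort_id": s.cohort_id,
                "n_tiles": s.n_tiles,
                "score": s.score,
                "label": s.label,
            }
            for s in scores
        ]
    )
    _atomic_write(path, df.to_csv(index=False, float_format="%.8f"))


def read_patient_scores(path: str | Path):
    from .types import PatientScore

    df = pd.read_csv(path)
    return [
        PatientScore(
            patient_id=str(r.patient_id),
            cohort_id=str(r.cohort_id),
            n_tiles=int(r.n_tiles),
            score=float(r.score),
            label=None if pd.isna(r.label) else int(r.label),
        )
        for r in df.itertuples()
    ]


def policy_to_yaml(policy) -> str:
    return yaml.safe_dump(
        {
            "kind": policy.kind,
            "value": float(policy.value),
            "target_sensitivity": policy.target_sensitivity,
            "provenance": policy.provenance,
        },
        sort_keys=True,
    )


def write_results(results, out_dir: str | Path, config: Optional[RunConfig] = None,
                  seed: Optional[int] = None) -> dict:
    """Write a cohort-results table, per-patient scores, policies and summary.

    ``results`` is a list of :class:`~msiprescreen.designs.CohortResult`.
    Every file embeds the config digest and seed; re-runs overwrite
    atomically, and identical (config, seed) runs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_digest": config.digest() if config else None,
        "seed": seed,
    }

    rows = []
    for r in results:
        row = {
            "cohort": r.cohort_id,
            "n_patients": r.n,
            "auroc": r.auroc,
            "auroc_ci_lower": r.auroc_ci.lower if r.auroc_ci else None,
            "auroc_ci_upper": r.auroc_ci.upper if r.auroc_ci else None,
        }
        for name, cs in r.confusion.items():
            row[f"{name}_threshold"] = r.policies[name].value
            row[f"{name}_sensitivity_pct"] = 100.0 * cs.sensitivity
            row[f"{name}_specificity_pct"] = 100.0 * cs.specificity
            row[f"{name}_ppv_pct"] = 100.0 * cs.ppv
            row[f"{name}_npv_pct"] = 100.0 * cs.npv
            row[f"{name}_ruleout_fraction"] = cs.ruleout_fraction
            row[f"{name}_fn_fraction"] = cs.fn_fraction
            row[f"{name}_f1"] = cs.f1
        rows.append(row)
    metrics_df = pd.DataFrame(rows)
    _atomic_write(out / "metrics.csv", metrics_df.to_csv(index=False, float_format="%.6f"))

    all_scores = [s for r in results for s in r.scores]
    write_patient_scores(all_scores, out / "patient_scores.csv")

    policies_text = "\n---\n".join(
        f"# cohort: {r.cohort_id} / policy: {name}\n" + policy_to_yaml(pol)
        for r in results
        for name, pol in r.policies.items()
    )
    _atomic_write(out / "policies.yaml", policies_text)

    summary = {
        **meta,
        "cohorts": [
            {
                "cohort_id": r.cohort_id,
                "n_patients": r.n,
                "auroc": r.auroc,
                "policies": {
                    name: {"value": pol.value, **r.confusion[name].as_dict()}
                    for name, pol in r.policies.items()
                },
            }
            for r in results
        ],
    }
    _atomic_write(out / "summary.json", json.dumps(summary, indent=2, sort_keys=True))
    return summary
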