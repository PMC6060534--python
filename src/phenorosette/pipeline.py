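"""End-to-end runs: images -> descriptors -> models -> predictions.

Three reproducible pipelines mirror the phenotyping workflow: dry mass
(tray/pot images -> rosette shape descriptors -> predictive model ->
per-plant mass estimates), fruit number (inflorescence images -> skeleton
descriptors -> model or the shipped reference equation -> per-plant fruit
estimates) and growth (estimated-mass series + final masses -> per-plant
logistic fits and inflection-point traits).

Failure policy: an unreadable or empty image is skipped and logged; a tray
run never aborts on one bad pot.  Every output CSV starts with a comment
line recording the package version, the seed and a hash of the
configuration, so identical runs are identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import imaging, models, skeleton

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_dry_mass_pipeline",
    "run_fruit_pipeline",
    "run_growth_pipeline",
    "measure_rosette_directory",
    "measure_skeleton_directory",
    "write_csv",
    "read_csv",
]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class RunConfig:
    """Configuration for a pipeline run."""

    input_dir: str
    output_dir: str
    segmentation: imaging.SegmentationConfig = field(
        default_factory=imaging.SegmentationConfig
    )
    px_per_cm: Optional[float] = None
    training_csv: Optional[str] = None  # plant_id + measured response
    response_col: str = "dry_mass"
    model_file: Optional[str] = None  # apply this model instead of training
    family: str = "linear"
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, cfg: Optional[RunConfig] = None) -> None:
    """Write a CSV with a provenance comment header (config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg is not None:
            fh.write(f"# phenorosette config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _iter_images(folder) -> list[Path]:
    folder = Path(folder)
    return sorted(
        p
        for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_SUFFIXES
    )


def _parse_day(name: str) -> float:
    # images named like tray01_day12.png carry the acquisition day
    for token in name.replace("-", "_").split("_"):
        if token.startswith("day"):
            try:
                return float(token[3:])
            except ValueError:
                pass
    return 0.0


def measure_rosette_directory(
    folder,
    cfg: imaging.SegmentationConfig,
    calib: Optional[imaging.Calibration] = None,
) -> pd.DataFrame:
    """Segment, label and measure every image in a folder; one row per
    plant x image.  Unreadable images are skipped and logged."""
    rows = []
    n_skipped = 0
    for path in _iter_images(folder):
        try:
            img = iio.imread(path)
        except Exception as exc:  # unreadable image: skip, keep the run alive
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            n_skipped += 1
            continue
        mask = imaging.segment_plants(img, cfg)
        labelmap = imaging.label_and_assign(mask, cfg)
        records = imaging.measure_rosette(
            labelmap,
            calib,
            day=_parse_day(path.stem),
            source_id=path.stem + "_",
        )
        for r in records:
            rows.append(
                {
                    "plant_id": r.plant_id,
                    "source_image": path.name,
                    "day": r.day,
                    "RA": r.RA,
                    "Perim": r.Perim,
                    "Circ": r.Circ,
                    "AR": r.AR,
                    "Round": r.Round,
                    "unit_flag": r.unit_flag,
                }
            )
    logger.info(
        "measured %d plant records from %s (%d images skipped)",
        len(rows),
        folder,
        n_skipped,
    )
    columns = [
        "plant_id",
        "source_image",
        "day",
        "RA",
        "Perim",
        "Circ",
        "AR",
        "Round",
        "unit_flag",
    ]
    return pd.DataFrame(rows, columns=columns)


def measure_skeleton_directory(
    folder,
    cfg: imaging.SegmentationConfig,
    calib: Optional[imaging.Calibration] = None,
) -> pd.DataFrame:
    """Segment, skeletonize and summarize every inflorescence image in a
    folder; one row per plant (image) with the nine descriptors."""
    rows = []
    for path in _iter_images(folder):
        try:
            img = iio.imread(path)
        except Exception as exc:
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            continue
        mask = imaging.segment_plants(img, cfg)
        skel = skeleton.skeletonize(mask)
        summary = skeleton.summarize_skeleton(skel, calib)
        row = {"plant_id": path.stem}
        row.update(summary.as_dict())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["plant_id", *skeleton.DESCRIPTOR_COLUMNS]
    )


def _resolve_model(
    cfg: RunConfig,
    descriptors: pd.DataFrame,
    predictor_cols: list[str],
    fallback: Optional[models.TraitModel],
) -> models.TraitModel:
    if cfg.model_file:
        return models.TraitModel.from_json(cfg.model_file)
    if cfg.training_csv:
        train = read_csv(cfg.training_csv)
        merged = descriptors.merge(train, on="plant_id", how="inner")
        if merged.empty:
            raise ValueError("no overlap between descriptors and training CSV")
        return models.fit(
            merged[predictor_cols],
            merged[cfg.response_col],
            family=cfg.family,
            on_collinear="drop",
        )
    if fallback is None:
        raise ValueError("no model file, training CSV, or reference model")
    logger.info("using the packaged reference model")
    return fallback


def _calib(cfg: RunConfig) -> Optional[imaging.Calibration]:
    return (
        imaging.Calibration(px_per_cm=cfg.px_per_cm) if cfg.px_per_cm else None
    )


def run_dry_mass_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Images -> rosette descriptors -> dry-mass model -> predictions.

    Writes rosette_descriptors.csv, dry_mass_model.json and
    predicted_mass.csv into the output folder and returns their paths.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    descriptors = measure_rosette_directory(
        cfg.input_dir, cfg.segmentation, _calib(cfg)
    )
    desc_path = out / "rosette_descriptors.csv"
    write_csv(descriptors, desc_path, cfg)

    predictor_cols = ["RA", "Circ"]
    model = _resolve_model(
        cfg, descriptors, predictor_cols, models.reference_dry_mass_model()
    )
    model_path = out / "dry_mass_model.json"
    model.to_json(model_path)

    pred = descriptors[["plant_id", "source_image", "day"]].copy()
    if len(descriptors):
        pred["predicted_dry_mass"] = models.predict(model, descriptors)
    else:
        pred["predicted_dry_mass"] = []
    pred_path = out / "predicted_mass.csv"
    write_csv(pred, pred_path, cfg)
    logger.info("dry-mass pipeline: %d predictions", len(pred))
    return {
        "descriptors": desc_path,
        "model": model_path,
        "predictions": pred_path,
    }


def run_fruit_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Inflorescence images -> nine skeleton descriptors -> fruit-number
    model -> predicted counts.  With neither training CSV nor model file,
    applies the packaged reference fruit equation."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    descriptors = measure_skeleton_directory(
        cfg.input_dir, cfg.segmentation, _calib(cfg)
    )
    desc_path = out / "skeleton_descriptors.csv"
    write_csv(descriptors, desc_path, cfg)

    reference = models.reference_fruit_model()
    predictor_cols = list(skeleton.DESCRIPTOR_COLUMNS)
    model = _resolve_model(cfg, descriptors, predictor_cols, reference)
    model_path = out / "fruit_model.json"
    model.to_json(model_path)

    pred = descriptors[["plant_id"]].copy()
    if len(descriptors):
        pred["predicted_fruit_number"] = models.predict(model, descriptors)
    else:
        pred["predicted_fruit_number"] = []
    pred_path = out / "predicted_fruit_number.csv"
    write_csv(pred, pred_path, cfg)
    logger.info("fruit pipeline: %d predictions", len(pred))
    return {
        "descriptors": desc_path,
        "model": model_path,
        "predictions": pred_path,
    }


def run_growth_pipeline(
    mass_csv,
    final_csv,
    output_dir,
    seed: int = 0,
) -> Path:
    """Estimated-mass series + final masses -> logistic fits and traits.

    ``mass_csv``: plant_id, day, estimated_mass.  ``final_csv``: plant_id,
    final_mass, maturity_day.  Plants that never reach the common size
    threshold (growth-start rule) are excluded and listed in the log.
    Writes growth_fits.csv (one row per plant) and returns its path.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    masses = read_csv(mass_csv)
    finals = read_csv(final_csv).set_index("plant_id")

    t0s, threshold, excluded = growth_mod.determine_t0(
        masses, size_col="estimated_mass"
    )
    if excluded:
        logger.warning(
            "%d plants excluded by the growth-start rule: %s",
            len(excluded),
            excluded,
        )
    rows = []
    for pid, g in masses.groupby("plant_id", sort=True):
        if pid not in t0s or pid not in finals.index:
            continue
        t0 = t0s[pid]
        g = g[g.day >= t0].sort_values("day")
        if len(g) < 3:
            logger.warning("plant %s has < 3 points after t0; skipped", pid)
            continue
        series = growth_mod.MassSeries(
            plant_id=str(pid),
            times=g.day.to_numpy() - t0,
            masses=g.estimated_mass.to_numpy(),
            A_final=float(finals.loc[pid, "final_mass"]),
            maturity_day=float(finals.loc[pid, "maturity_day"]),
        )
        fit = growth_mod.fit_logistic(series, t0=t0)
        traits = growth_mod.traits_at_inflection(fit)
        rows.append(
            {
                "plant_id": fit.plant_id,
                "A": fit.A,
                "B": fit.B,
                "t_inf": fit.t_inf,
                "r": fit.r,
                "t0": fit.t0,
                "duration": fit.duration,
                "rss": fit.rss,
                "converged": fit.converged,
                "M_at_tinf": traits.M_at_tinf,
                "GR_at_tinf": traits.GR_at_tinf,
                "RGR_at_tinf": traits.RGR_at_tinf,
                "RGR_at_tinf_mg_per_g": traits.RGR_at_tinf
                * growth_mod.RGR_PER_GRAM,
            }
        )
    fits = pd.DataFrame(rows)
    path = out / "growth_fits.csv"
    cfg = RunConfig(input_dir=str(mass_csv), output_dir=str(out), seed=seed)
    write_csv(fits, path, cfg)
    logger.info(
        "growth pipeline: %d fits, threshold %.3g, %d excluded",
        len(fits),
        threshold,
        len(excluded),
    )
    return path
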