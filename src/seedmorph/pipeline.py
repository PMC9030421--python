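"""End-to-end run: simulate -> render -> segment -> measure -> classify.

``run_pipeline`` mirrors the full study design on synthetic material: a
labelled multi-class population and an unknown cohort are rendered onto
scanner-style images, re-segmented, measured, and fed through stepwise
discriminant analysis; the outputs are the feature table, the
cross-validated allocation table, the unknown-cohort allocation row, the
fitted model and a provenance record of the resolved configuration.

Every random draw flows through the single seed in :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from . import classify as cls
from . import synthetic as syn
from .errors import InputError, ValidationError
from .morphometry import FeatureTable, extract_features
from .segmentation import SeedMask, segment_seeds

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("seedmorph")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    out_dir: str
    spec_path: str | None = None
    specs: list[syn.ShapeClassSpec] = field(default_factory=list)
    unknown: dict | None = None  # {"from_class": name, "n": count}
    seed: int = 7
    dpi: float = 400.0
    units: str = "px"
    min_area_px: int = 50
    spacing_px: int = 20
    f_to_enter: float = 3.84
    f_to_remove: float = 2.71
    tolerance: float = 0.001
    priors: str = "equal"
    cv_scheme: str = "loo"
    kfold_k: int = 5
    honest_cv: bool = False
    log_level: str = "INFO"

    def stepwise_config(self) -> cls.StepwiseConfig:
        return cls.StepwiseConfig(
            tolerance=self.tolerance,
            f_to_enter=self.f_to_enter,
            f_to_remove=self.f_to_remove,
            priors=self.priors,
        )

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["specs"] = [dataclasses.asdict(s) for s in self.specs]
        return d


def simulate_and_scan(
    config: RunConfig,
) -> tuple[syn.SyntheticPopulation, syn.SyntheticPopulation | None, dict]:
    """Sample the labelled population and the optional unknown cohort."""
    specs = config.specs
    unknown = config.unknown
    if config.spec_path is not None:
        specs, unknown = syn.specs_from_json(config.spec_path)
    if not specs:
        raise ValidationError("no shape-class specs given")
    population = syn.sample_population(specs, dpi=config.dpi, seed=config.seed)

    unknown_pop = None
    if unknown is not None:
        by_name = {s.name: s for s in specs}
        src = by_name.get(unknown["from_class"])
        if src is None:
            raise ValidationError(
                f"unknown cohort references missing class {unknown['from_class']!r}"
            )
        cohort_spec = dataclasses.replace(src, name=src.name, n=int(unknown["n"]))
        unknown_pop = syn.sample_population(
            [cohort_spec], dpi=config.dpi, seed=config.seed + 1000
        )
        for m in unknown_pop.masks:
            m.class_label = "UNKNOWN"
            m.specimen_id = m.specimen_id.replace(src.name, "unknown")
    return population, unknown_pop, {"specs": specs, "unknown": unknown}


def rescan_population(
    population: syn.SyntheticPopulation,
    config: RunConfig,
    background_mode: str = "white",
) -> list[SeedMask]:
    """Render each class onto its own scan and segment it back out.

    Scanning class by class mirrors how physical accessions are imaged one
    seed lot at a time, and lets the recovered masks inherit the class
    label of their scan.  Raises if the seed count recovered from a scan
    differs from the count placed on it.
    """
    by_class: dict[str, list[SeedMask]] = {}
    for m in population.masks:
        by_class.setdefault(m.class_label, []).append(m)

    recovered: list[SeedMask] = []
    for label, masks in by_class.items():
        sub = syn.SyntheticPopulation(
            masks=masks, truth=population.truth, seed=population.seed, dpi=population.dpi
        )
        image, _ = syn.render_scan(
            sub,
            layout=syn.ScanLayout(spacing_px=config.spacing_px),
            background_mode=background_mode,
        )
        found = segment_seeds(
            image,
            min_area_px=config.min_area_px,
            exclude_border=False,
            source_id=f"scan:{label}",
        )
        if len(found) != len(masks):
            raise ValidationError(
                f"scan of class {label!r}: placed {len(masks)} seeds but segmented "
                f"{len(found)}"
            )
        for m in found:
            m.class_label = label
        recovered.extend(found)
    return recovered


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out_dir = Path(config.out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    population, unknown_pop, resolved = simulate_and_scan(config)
    logger.info("simulated %d labelled seeds", len(population.masks))

    masks = rescan_population(population, config)
    if unknown_pop is not None:
        unknown_masks = rescan_population(unknown_pop, config)
        for m in unknown_masks:
            m.class_label = "UNKNOWN"
        masks = masks + unknown_masks
    logger.info("segmentation recovered %d masks", len(masks))

    table = extract_features(masks, units=config.units, dpi=config.dpi)
    features_csv = out_dir / "features.csv"
    table.to_csv(features_csv)
    logger.info(
        "measured %d specimens (%d rejected)", len(table), len(table.rejects)
    )

    sw_config = config.stepwise_config()
    selected, step_log = cls.stepwise_select(table, sw_config)
    logger.info("stepwise selection kept %d descriptors: %s", len(selected), selected)
    model = cls.fit_lda(table, selected, priors=config.priors)
    model.to_json(out_dir / "model.json")

    cv_table = cls.cross_validate(
        table,
        sw_config,
        scheme=config.cv_scheme,
        k=config.kfold_k,
        seed=config.seed,
        features=None if config.honest_cv else selected,
        reselect_per_fold=config.honest_cv,
    )
    tables = {"cross_validation": cv_table}

    allocation = posteriors = None
    if unknown_pop is not None:
        allocation, posteriors = cls.allocate_unknowns(model, table)
        tables["unknown_allocation"] = allocation
        posteriors.to_csv(out_dir / "unknown_posteriors.csv", index=False)

    cls.write_report(tables, out_dir, step_log=step_log)

    provenance = {
        "seedmorph_version": _package_version(),
        "resolved_config": config.to_json(),
        "counts": {
            "simulated": len(population.masks)
            + (len(unknown_pop.masks) if unknown_pop else 0),
            "segmented": len(masks),
            "measured": len(table),
            "rejected": len(table.rejects),
            "selected_features": len(selected),
            "cv_folds": int(cv_table.counts.sum()),
        },
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    return {
        "feature_table": table,
        "selected_features": selected,
        "step_log": step_log,
        "model": model,
        "cv_table": cv_table,
        "allocation": allocation,
        "posteriors": posteriors,
        "out_dir": out_dir,
    }
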