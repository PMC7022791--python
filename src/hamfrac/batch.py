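"""Batch orchestration: config validation, end-to-end runs, manifests.

A run takes a set of images — synthetic fixture classes or real
photographs with crop windows — and, for each image and each requested
segmentation method, writes the binary mask (PNG), optionally the
three-column pixel table (CSV), and the sandbox dimension record
(JSON); it then aggregates everything into the summary tables.  A
manifest written last records per-image provenance, output paths and a
canonical config hash, so a run can be audited and re-created from the
manifest alone.

One seed in the config determines the fixture, every sandbox draw and
hence every output byte (the manifest's wall-clock timestamp aside).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np

from . import io as hio
from .pipeline import FilterConfig, crop_square, fat_fraction, mask_to_table, run_method
from .sandbox import MaskAnalysis, SandboxConfig, analyze_mask
from .summary import (
    METHODS,
    ImageResult,
    boxplot_table,
    dispersion_comparison,
    scatter_table,
    summarize,
)
from .synthetic import SliceParams, make_class_fixture

__all__ = ["ConfigError", "RunConfig", "RunManifest", "validate_config", "run_batch",
           "analysis_record", "result_from_analysis"]

logger = logging.getLogger("hamfrac")


class ConfigError(ValueError):
    """A run configuration failed validation; the message names the field."""


@dataclass(frozen=True)
class FixtureSpec:
    classes: dict[str, SliceParams]
    n_per_class: int = 10


@dataclass(frozen=True)
class InputSpec:
    path: str
    crop: tuple[int, int] = (0, 0)
    class_label: str = "unlabelled"


@dataclass(frozen=True)
class RunConfig:
    methods: tuple[str, ...] = METHODS
    filter: FilterConfig = field(default_factory=FilterConfig)
    sandbox: SandboxConfig = field(default_factory=SandboxConfig)
    fixture: FixtureSpec | None = None
    inputs: tuple[InputSpec, ...] = ()
    out_dir: str = "results/run"
    seed: int = 0
    write_pixel_tables: bool = True

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("methods: at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"methods: unknown {sorted(unknown)}; choose from {METHODS}")
        if self.fixture is None and not self.inputs:
            raise ConfigError("either a synthetic fixture or input images must be given")


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    created_utc: str
    images: list[dict]
    summary_files: list[str]
    errors: list[dict]
    notes: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def _build(cls, raw: dict, path: str):
    """Construct a config dataclass from a dict, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(raw).__name__}")
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(raw: dict) -> RunConfig:
    """Turn a parsed YAML/JSON mapping into a validated RunConfig.

    Defaults (high-pass radii presets 25/50, thresholds 175/150, 512-px
    crop, sandbox defaults) are filled for anything omitted; unknown
    keys and out-of-range values are reported with their field path.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config: expected a mapping at the top level")
    raw = dict(raw)
    kwargs: dict[str, Any] = {}
    if "filter" in raw:
        kwargs["filter"] = _build(FilterConfig, raw.pop("filter"), "filter")
    if "sandbox" in raw:
        sb = dict(raw.pop("sandbox"))
        if "q_values" in sb:
            sb["q_values"] = tuple(float(q) for q in sb["q_values"])
        kwargs["sandbox"] = _build(SandboxConfig, sb, "sandbox")
    if "fixture" in raw:
        fx = dict(raw.pop("fixture"))
        classes_raw = fx.pop("classes", None)
        if not classes_raw:
            raise ConfigError("fixture.classes: at least one class is required")
        classes = {
            str(label): _build(SliceParams, dict(spec), f"fixture.classes.{label}")
            for label, spec in classes_raw.items()
        }
        fx["classes"] = classes
        kwargs["fixture"] = _build(FixtureSpec, fx, "fixture")
    if "inputs" in raw:
        items = raw.pop("inputs")
        specs = []
        for i, item in enumerate(items):
            item = dict(item)
            if "crop" in item:
                item["crop"] = tuple(int(v) for v in item["crop"])
            specs.append(_build(InputSpec, item, f"inputs[{i}]"))
        kwargs["inputs"] = tuple(specs)
    if "methods" in raw:
        kwargs["methods"] = tuple(raw.pop("methods"))
    for key in ("out_dir", "seed", "write_pixel_tables"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigError(f"config: unknown keys {sorted(raw)}")
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical (sorted-key) JSON form; field order immaterial."""
    canonical = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _derived_seed(base: int, *indices: int) -> int:
    return int(np.random.SeedSequence([base, *indices]).generate_state(1)[0] % 2**31)


def analysis_record(analysis: MaskAnalysis, **extra) -> dict:
    """JSON-ready per-mask record: estimates, fat fraction, config echo."""
    return {
        "estimates": [asdict(e) for e in analysis.estimates],
        "fat_fraction": analysis.fat_fraction,
        "config": asdict(analysis.config),
        **extra,
    }


def result_from_analysis(
    analysis: MaskAnalysis, image_id: str, class_label: str, method: str,
    mask_fat_fraction: float,
) -> ImageResult:
    return ImageResult(
        image_id=image_id,
        class_label=class_label,
        method=method,
        d0=analysis.dimension(0.0),
        d1=analysis.dimension(1.0),
        d2=analysis.dimension(2.0),
        fat_fraction=mask_fat_fraction,
    )


def _gather_images(cfg: RunConfig) -> list[tuple[str, str, np.ndarray, dict]]:
    """Materialize (image_id, class_label, rgb, provenance) for the run."""
    out = []
    if cfg.fixture is not None:
        samples = make_class_fixture(cfg.fixture.classes, cfg.fixture.n_per_class, cfg.seed)
        counters: dict[str, int] = {}
        for s in samples:
            k = counters.get(s.class_label, 0)
            counters[s.class_label] = k + 1
            image_id = f"{s.class_label}_{k:03d}"
            out.append((image_id, s.class_label,
                        s.image, {"source": "synthetic", "params": asdict(s.params)}))
    for spec in cfg.inputs:
        rgb = hio.load_image(spec.path)
        rgb = crop_square(rgb, spec.crop, cfg.filter.crop_side)
        image_id = Path(spec.path).stem
        out.append((image_id, spec.class_label, rgb,
                    {"source": spec.path, "crop": list(spec.crop)}))
    return out


def run_batch(cfg: RunConfig) -> RunManifest:
    """Execute the full pipeline for every image x method in the config.

    Per-image failures are logged and recorded in the manifest but do
    not abort the batch; the manifest is written last so its presence
    marks a completed run.
    """
    out_dir = Path(cfg.out_dir)
    for sub in ("masks", "tables", "mfa"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    images = _gather_images(cfg)
    records: list[dict] = []
    errors: list[dict] = []
    results: list[ImageResult] = []
    for idx, (image_id, class_label, rgb, provenance) in enumerate(images):
        rec = {"image_id": image_id, "class_label": class_label,
               "provenance": provenance, "outputs": {}}
        for m_idx, method in enumerate(cfg.methods):
            try:
                mask = run_method(rgb, method, cfg.filter)
                frac = fat_fraction(mask)
                sb = replace(cfg.sandbox, seed=_derived_seed(cfg.seed, idx, m_idx))
                analysis = analyze_mask(mask, sb)
                # manifest paths are relative to out_dir so runs relocate cleanly
                mask_rel = f"masks/{image_id}_{method}.png"
                hio.save_mask_png(mask, out_dir / mask_rel)
                outputs = {"mask_png": mask_rel}
                if cfg.write_pixel_tables:
                    table_rel = f"tables/{image_id}_{method}.csv"
                    hio.write_pixel_table(mask_to_table(mask), out_dir / table_rel)
                    outputs["table_csv"] = table_rel
                mfa_rel = f"mfa/{image_id}_{method}.json"
                hio.write_json(
                    analysis_record(analysis, image_id=image_id, method=method,
                                    class_label=class_label),
                    out_dir / mfa_rel,
                )
                outputs["mfa_json"] = mfa_rel
                rec["outputs"][method] = outputs
                results.append(
                    result_from_analysis(analysis, image_id, class_label, method, frac)
                )
                logger.info("processed %s with %s (fat fraction %.3f)",
                            image_id, method, frac)
            except Exception as exc:  # per-image robustness: record and continue
                logger.warning("failed %s with %s: %s", image_id, method, exc)
                errors.append({"image_id": image_id, "method": method, "error": str(exc)})
        records.append(rec)

    summary_files: list[str] = []
    notes: list[str] = []
    if results:
        csv_kw = dict(index=False, lineterminator="\n")
        scatter_table(results).to_csv(out_dir / "scatter.csv", **csv_kw)
        summary_files.append("scatter.csv")
        try:
            summarize(results).to_csv(out_dir / "summary.csv", **csv_kw)
            summary_files.append("summary.csv")
        except ValueError as exc:
            notes.append(f"summary skipped: {exc}")
        try:
            boxplot_table(results).to_csv(out_dir / "boxstats.csv", **csv_kw)
            summary_files.append("boxstats.csv")
            dispersion_comparison(results).to_csv(out_dir / "dispersion.csv", **csv_kw)
            summary_files.append("dispersion.csv")
        except ValueError as exc:
            notes.append(f"dispersion/boxstats skipped: {exc}")

    manifest = RunManifest(
        config=asdict(cfg),
        config_hash=config_hash(cfg),
        created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        images=records,
        summary_files=summary_files,
        errors=errors,
        notes=notes,
    )
    hio.write_json(asdict(manifest) | {"ok": manifest.ok}, out_dir / "manifest.json")
    return manifest
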