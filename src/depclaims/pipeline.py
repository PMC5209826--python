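"""Pipeline orchestration: generate/load → select → attribute → profile → report.

A :class:`PipelineConfig` points either at a directory of claims CSV files or
at the synthetic generator, fixes the study year, thresholds, code-set
registry and attribution order, and :func:`run_pipeline` produces a report
bundle in the output directory:

* ``selection/ids_<sub_source>.txt`` — sorted id list per sub-source, plus
  the excluded set;
* ``attribution.csv`` — incremental/cumulative counts (raw and rounded to
  the nearest 5) and cumulative prevalence per source row;
* ``overlap.json`` — the 7-region partition of the aggregate A/B/C sets,
  the multi-source fraction, and per-method overlap rates;
* ``profiles.csv`` — cohort profile per sub-source and for the combined
  A+B+C selected population;
* ``manifest.json`` — config hash, seed, registry hash and raw counts.

All outputs are deterministic given the config (byte-stable across runs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import attribution as attr
from .characteristics import profile_cohort
from .code_sets import default_registry, load_registry
from .data_model import ClaimsBundle, read_bundle, write_bundle
from .selection import SUB_SOURCE_LABELS, SelectionConfig, SelectionResult, run_selection
from .synthetic import generate, calibrated_params

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("depclaims")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable, CLI-overridable)."""

    input_dir: Path | None = None
    generator_n: int | None = None
    study_year: int = 2012
    registry_path: Path | None = None
    ad_min_dispensings: int = Field(default=3, ge=1)
    bipolar_drug_min_dispensings: int = Field(default=1, ge=1)
    order: list[str] | None = None
    output_dir: Path = Path("depclaims_out")
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_input(self):
        if (self.input_dir is None) == (self.generator_n is None):
            raise ValueError("exactly one of input_dir / generator_n must be set")
        if not 1000 <= self.study_year <= 9999:
            raise ValueError("study_year must be a 4-digit year")
        return self

    def selection_config(self) -> SelectionConfig:
        registry = (
            load_registry(self.registry_path) if self.registry_path else default_registry()
        )
        return SelectionConfig(
            ad_min_dispensings=self.ad_min_dispensings,
            bipolar_drug_min_dispensings=self.bipolar_drug_min_dispensings,
            registry=registry,
        )


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file, applying keyword overrides on top."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


def _config_dump(config: PipelineConfig) -> dict:
    # output_dir is where the manifest itself lives; keeping it out of the
    # manifest makes reports byte-identical across output locations
    dump = config.model_dump(mode="json")
    dump.pop("output_dir")
    return dump


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_config_dump(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _registry_hash(config: PipelineConfig) -> str:
    if config.registry_path:
        blob = Path(config.registry_path).read_bytes()
    else:
        from importlib import resources

        blob = resources.files("depclaims").joinpath("code_registry.yaml").read_bytes()
    return hashlib.sha256(blob).hexdigest()[:16]


def _acquire_bundle(config: PipelineConfig) -> ClaimsBundle:
    if config.input_dir is not None:
        log.info("reading bundle from %s", config.input_dir)
        return read_bundle(config.input_dir, config.study_year)
    log.info("generating synthetic bundle (n=%d, seed=%d)", config.generator_n, config.seed)
    params = calibrated_params(config.generator_n, config.study_year, config.seed)
    return generate(params)


def _write_id_lists(selection: SelectionResult, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for label, ids in selection.sets().items():
        (directory / f"ids_{label}.txt").write_text(
            "".join(f"{i}\n" for i in sorted(ids)), encoding="utf-8"
        )
    (directory / "ids_excluded_bipolar.txt").write_text(
        "".join(f"{i}\n" for i in sorted(selection.excluded_bipolar)), encoding="utf-8"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the in-memory results and writes the
    report bundle under ``config.output_dir``."""
    logging.basicConfig(level=config.log_level.upper())
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel_config = config.selection_config()

    try:
        bundle = _acquire_bundle(config)
    except Exception:
        log.exception("stage failed: acquire bundle")
        raise
    if config.generator_n is not None:
        write_bundle(bundle, out / "bundle")

    try:
        selection = run_selection(bundle, sel_config)
    except Exception:
        log.exception("stage failed: selection")
        raise
    _write_id_lists(selection, out / "selection")
    log.info(
        "selection: %s of %d beneficiaries excluded as bipolar",
        len(selection.excluded_bipolar), selection.denominator_count,
    )

    try:
        attribution = attr.attribute_incremental(selection, config.order)
    except Exception:
        log.exception("stage failed: attribution")
        raise
    attribution.to_frame().to_csv(out / "attribution.csv", index=False)

    methods = selection.method_sets()
    venn = attr.venn_partition(methods["A"], methods["B"], methods["C"])
    rates = attr.multi_source_rates(selection)
    overlap = {
        "regions": venn.to_dict(),
        "union_size": venn.union_size,
        "multi_source_fraction": venn.multi_source_fraction,
        "per_method_overlap_rates": rates,
    }
    (out / "overlap.json").write_text(
        json.dumps(overlap, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    try:
        profiles = {}
        for label, ids in selection.sets().items():
            profiles[label] = profile_cohort(bundle, ids, sel_config).to_series()
        selected_abc = methods["A"] | methods["B"] | methods["C"]
        profiles["selected_ABC"] = profile_cohort(bundle, selected_abc, sel_config).to_series()
    except Exception:
        log.exception("stage failed: profiling")
        raise
    profile_frame = pd.DataFrame(profiles)
    profile_frame.to_csv(out / "profiles.csv")

    manifest = {
        "config": _config_dump(config),
        "config_hash": _config_hash(config),
        "registry_hash": _registry_hash(config),
        "seed": config.seed,
        "denominator": selection.denominator_count,
        "excluded_bipolar": len(selection.excluded_bipolar),
        "counts_raw": {label: len(ids) for label, ids in selection.sets().items()},
        "counts_rounded": {
            label: attr.round_to_nearest_5(len(ids))
            for label, ids in selection.sets().items()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return {
        "bundle": bundle,
        "selection": selection,
        "attribution": attribution,
        "overlap": overlap,
        "profiles": profile_frame,
        "manifest": manifest,
        "output_dir": out,
    }
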