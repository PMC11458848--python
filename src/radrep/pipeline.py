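"""End-to-end pipeline: simulate (or ingest) -> prep -> perturb -> extract ->
ICC -> volume filter -> median split -> per-group selection and Cox fits for
both endpoints -> evaluation on training and validation cohorts -> optional
ICC-threshold sweep.

The pipeline is driven by a single :class:`PipelineConfig`; a global seed
deterministically derives every sub-seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ImageVolume, ROIMask
from .features.engine import ExtractionConfig, extract_table, mesh_volume
from .modeling import RadiomicsCoxModel, RadiomicsCoxResults, icc_threshold_sweep
from .perturb import PerturbationSpec, generate_perturbation_set
from .preprocess import resample_isotropic
from .repeatability import (
    RepeatabilityGroups,
    RepeatabilityTable,
    compute_feature_icc,
    split_by_median_icc,
)
from .selection import SelectionConfig
from .synthetic import CensoringSpec, EffectSpec, PhantomSpec, SyntheticCohort, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "reduced_scale_config"]

ENDPOINTS = ("lrfs", "os")


@dataclass
class PipelineConfig:
    """Everything one run needs.  Unknown keys are rejected on load."""

    n_train: int = 60
    n_validation: int = 30
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    site_shift: dict | None = None
    effects: dict[str, EffectSpec] | None = None
    endpoints: tuple[str, ...] = ENDPOINTS
    run_sweep: bool = False
    sweep_bin_width: float = 8.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key, typ in [("phantom", PhantomSpec), ("perturbation", PerturbationSpec),
                         ("selection", SelectionConfig), ("censoring", CensoringSpec)]:
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d[key].items()})
        if "effects" in d and isinstance(d["effects"], dict):
            d["effects"] = {k: EffectSpec(**v) if isinstance(v, dict) else v
                            for k, v in d["effects"].items()}
        if "endpoints" in d:
            d["endpoints"] = tuple(d["endpoints"])
        return cls(**d)


def reduced_scale_config(seed: int = 0, run_sweep: bool = False) -> PipelineConfig:
    """A desk-scale two-site configuration: 60 + 30 patients, 32^3 grids,
    original + wavelet filter bank, bin widths {8, 128}, 3 perturbation
    realizations.  Small enough to run end to end in a few minutes while
    preserving every qualitative contrast of the full design."""
    from .preprocess import WAVELET_SUBBANDS, FilterSpec

    filters = tuple(
        [FilterSpec("original")] + [FilterSpec("wavelet", subband=b) for b in WAVELET_SUBBANDS]
    )
    return PipelineConfig(
        n_train=60,
        n_validation=30,
        phantom=PhantomSpec(grid_shape=(32, 32, 32), tumor_radii_mm=(9.0, 8.0, 7.0)),
        perturbation=PerturbationSpec(n_realizations=3, seed=seed),
        extraction=ExtractionConfig(filters=filters, bin_widths=(8.0, 128.0)),
        selection=SelectionConfig(n_folds=5),
        run_sweep=run_sweep,
        seed=seed,
    )


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    config: PipelineConfig
    cohort: SyntheticCohort
    features_train: pd.DataFrame
    features_validation: pd.DataFrame
    perturbed_tables: list[pd.DataFrame]
    volumes: pd.Series
    repeatability: RepeatabilityTable
    volume_removed: tuple[str, ...]
    volume_retained: tuple[str, ...]
    groups: RepeatabilityGroups
    models: dict[tuple[str, str], RadiomicsCoxResults]  # (endpoint, group)
    evaluations: dict[tuple[str, str, str], dict]  # (endpoint, group, cohort)
    sweep: dict[str, pd.DataFrame] | None
    manifest: dict

    def summary_frame(self) -> pd.DataFrame:
        """The Table-2-style consolidated comparison (C-index per block)."""
        rows = []
        for (endpoint, group, cohort), ev in self.evaluations.items():
            rows.append({
                "endpoint": endpoint, "group": group, "cohort": cohort,
                "c_index": ev["c_index"], "n_features": ev["n_features"],
                "hazard_ratio": ev.get("hazard_ratio"),
            })
        return pd.DataFrame(rows)


def _prep_case(img: ImageVolume, msk: ROIMask):
    return resample_isotropic(img, msk)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(10).to_csv().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow on a synthetic two-site cohort."""
    t_start = _time.time()
    timings: dict[str, float] = {}

    # --- simulate ---------------------------------------------------------
    cohort = generate_cohort(
        n_train=config.n_train,
        n_validation=config.n_validation,
        base_phantom=config.phantom,
        effects=config.effects,
        censoring=config.censoring,
        site_shift=config.site_shift,
        seed=config.seed,
    )
    table = cohort.table
    train_ids = list(table.index[table["site"] == "train"])
    val_ids = list(table.index[table["site"] == "validation"])
    timings["simulate"] = _time.time() - t_start

    # --- prep + extract originals ----------------------------------------
    t0 = _time.time()
    prepped = {pid: _prep_case(*cohort.images[pid]) for pid in table.index}
    features_train = extract_table(
        ((pid, *prepped[pid]) for pid in train_ids), config.extraction
    )
    features_validation = extract_table(
        ((pid, *prepped[pid]) for pid in val_ids), config.extraction
    )
    volumes = pd.Series(
        {pid: mesh_volume(prepped[pid][1]) for pid in table.index}, name="mesh_volume"
    )
    timings["extract_original"] = _time.time() - t0

    # --- perturb + extract (training set only, as in the study design) ----
    t0 = _time.time()
    perturbed_tables: list[pd.DataFrame] = []
    per_patient: dict[str, list] = {pid: [] for pid in train_ids}
    for i, pid in enumerate(train_ids):
        spec = PerturbationSpec(
            rotation_range_deg=config.perturbation.rotation_range_deg,
            n_realizations=config.perturbation.n_realizations,
            supervoxel_target_volume=config.perturbation.supervoxel_target_volume,
            randomize_contour=config.perturbation.randomize_contour,
            seed=int(np.random.SeedSequence(
                entropy=config.seed, spawn_key=(7, i)).generate_state(1)[0] % 2**31),
        )
        img, msk = prepped[pid]
        per_patient[pid] = generate_perturbation_set(img, msk, spec)
    for r in range(config.perturbation.n_realizations):
        tab = extract_table(
            ((pid, per_patient[pid][r].image, per_patient[pid][r].mask) for pid in train_ids),
            config.extraction,
        )
        perturbed_tables.append(tab)
    timings["perturb_extract"] = _time.time() - t0

    # --- ICC + volume filter + median split -------------------------------
    t0 = _time.time()
    repeatability = compute_feature_icc(features_train, perturbed_tables)
    from .selection import volume_dependency_filter

    removed, retained, r2 = volume_dependency_filter(
        features_train, volumes.loc[train_ids], config.selection.r2_threshold
    )
    groups = split_by_median_icc(repeatability, list(retained))
    timings["icc_grouping"] = _time.time() - t0

    # --- per endpoint x group: selection + Cox + evaluation ---------------
    t0 = _time.time()
    models: dict[tuple[str, str], RadiomicsCoxResults] = {}
    evaluations: dict[tuple[str, str, str], dict] = {}
    surv = {
        "train": table.loc[train_ids],
        "validation": table.loc[val_ids],
    }
    feats = {"train": features_train, "validation": features_validation}
    for endpoint in config.endpoints:
        for gname, fids in (("high", groups.high), ("low", groups.low)):
            model = RadiomicsCoxModel(
                features_train[list(fids)],
                surv["train"][f"{endpoint}_time"],
                surv["train"][f"{endpoint}_event"],
                config=config.selection,
            )
            res = model.fit(seed=config.seed)
            models[(endpoint, gname)] = res
            for cname in ("train", "validation"):
                ev = res.evaluate(
                    feats[cname][list(fids)],
                    surv[cname][f"{endpoint}_time"],
                    surv[cname][f"{endpoint}_event"],
                    n_bootstrap=0,
                )
                evaluations[(endpoint, gname, cname)] = {
                    "c_index": ev.c_index,
                    "auc": ev.auc,
                    "km_logrank_p": ev.km_logrank_p,
                    "hazard_ratio": ev.risk_strata.hazard_ratio if ev.risk_strata else None,
                    "n_features": len(res.selected_features),
                    "n": ev.n,
                }
    timings["modeling"] = _time.time() - t0

    # --- ICC threshold sweep (optional) -----------------------------------
    sweep = None
    if config.run_sweep:
        t0 = _time.time()
        sweep = {}
        bw = config.sweep_bin_width
        sweep_cols = [c for c in retained
                      if f"_bw{bw:g}_" in c]
        for endpoint in config.endpoints:
            sweep[endpoint] = icc_threshold_sweep(
                features_train[sweep_cols],
                features_validation[sweep_cols],
                surv["train"][f"{endpoint}_time"],
                surv["train"][f"{endpoint}_event"],
                surv["validation"][f"{endpoint}_time"],
                surv["validation"][f"{endpoint}_event"],
                repeatability.icc,
                config=config.selection,
                seed=config.seed,
            )
        timings["sweep"] = _time.time() - t0

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "checksums": {
            "features_train": _checksum(features_train),
            "features_validation": _checksum(features_validation),
            "icc": hashlib.sha256(
                repeatability.icc.round(12).to_csv().encode()
            ).hexdigest()[:16],
        },
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "n_features": int(features_train.shape[1]),
        "volume_filter": {"removed": len(removed), "retained": len(retained)},
        "median_icc_cutoff": groups.cutoff,
    }

    return PipelineResult(
        config=config,
        cohort=cohort,
        features_train=features_train,
        features_validation=features_validation,
        perturbed_tables=perturbed_tables,
        volumes=volumes,
        repeatability=repeatability,
        volume_removed=removed,
        volume_retained=retained,
        groups=groups,
        models=models,
        evaluations=evaluations,
        sweep=sweep,
        manifest=manifest,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["extraction"] = {
        "filters": [f.name for f in config.extraction.filters],
        "bin_widths": list(config.extraction.bin_widths),
        "families": list(config.extraction.families),
        "window": config.extraction.window,
        "wavelet": config.extraction.wavelet,
    }
    return d
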