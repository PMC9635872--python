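"""Config-driven orchestration of the full atlas build.

A single YAML config describes the inputs (per-embryo channel stacks and
per-user annotation tables), the reference stack, thresholds and stage
parameters; :func:`run_atlas_build` then executes
register -> segment -> consensus -> quantify and writes the label
3D-model, per-stage CSV tables and a machine-readable provenance log.
:func:`run_birthdate_build` drives the birthdating track from registered
photoconversion masks.  All randomness is seeded from one root seed, so a
re-run with the same config reproduces identical outputs; the provenance
log records everything needed to do so.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import VoxelSpacing
from .errors import AtlasError, ConfigError
from .io import read_mask, read_stack, write_mask, write_transform
from .quantify import (
    RegressionConfig,
    axis_profile,
    mask_volume,
    smooth_profile,
    variability_to_model,
)
from .registration import RegistrationConfig, apply_transform, register_rigid
from .segmentation import (
    Annotation,
    UserVolumeTable,
    compute_features,
    flag_outlier_users,
    segment_volume,
    train_classifier,
)
from .consensus import average_masks, build_label_model, threshold_consensus
from .birthdating import (
    build_birthdate_map,
    interval_growth_table,
    population_birthdates,
)

log = logging.getLogger(__name__)


@dataclass
class EmbryoSpec:
    id: str
    channels: list[str]
    annotations: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml`` for the schema)."""

    output_dir: Path
    seed: int = 0
    reference_stack: str | None = None
    reference_model: str | None = None
    signal_channel: int = 1
    embryos: list[EmbryoSpec] = field(default_factory=list)
    user_k: object = "all"
    embryo_k: int = 3
    scales: tuple = (1, 2, 4)
    axes: tuple = ("AP",)
    smoothing: object = "cv"
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    default_spacing: VoxelSpacing = field(
        default_factory=lambda: VoxelSpacing(1.0, 1.0, 1.0)
    )
    # birthdating track
    total_mask: str | None = None
    photoconversions: list[dict] = field(default_factory=list)
    acquisition_hpf: float | None = None
    enforce_nesting: bool = True
    populations: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        base = Path(base) if base else Path(".")

        def resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        embryos = [
            EmbryoSpec(
                id=str(e.get("id", f"e{i + 1}")),
                channels=[resolve(c) for c in e.get("channels", [])],
                annotations=[resolve(a) for a in e.get("annotations", [])],
            )
            for i, e in enumerate(raw.get("embryos", []))
        ]
        thresholds = raw.get("thresholds", {})
        reg = RegistrationConfig(**raw.get("registration", {}))
        spacing = raw.get("default_spacing")
        spacing = VoxelSpacing(*spacing) if spacing else VoxelSpacing(1.0, 1.0, 1.0)
        return cls(
            output_dir=Path(resolve(raw.get("output_dir", "atlas_out"))),
            seed=int(raw.get("seed", 0)),
            reference_stack=resolve(raw["reference_stack"]) if raw.get("reference_stack") else None,
            reference_model=resolve(raw["reference_model"]) if raw.get("reference_model") else None,
            signal_channel=int(raw.get("signal_channel", 1)),
            embryos=embryos,
            user_k=thresholds.get("user_k", "all"),
            embryo_k=int(thresholds.get("embryo_k", 3)),
            scales=tuple(raw.get("scales", (1, 2, 4))),
            axes=tuple(raw.get("axes", ("AP",))),
            smoothing=raw.get("smoothing", "cv"),
            registration=reg,
            default_spacing=spacing,
            total_mask=resolve(raw["total_mask"]) if raw.get("total_mask") else None,
            photoconversions=[
                {"time": float(p["time"]), "mask": resolve(p["mask"])}
                for p in raw.get("photoconversions", [])
            ],
            acquisition_hpf=(
                float(raw["acquisition_time"]) if raw.get("acquisition_time") is not None else None
            ),
            enforce_nesting=bool(raw.get("enforce_nesting", True)),
            populations=[
                {"id": str(p["id"]), "mask": resolve(p["mask"])}
                for p in raw.get("populations", [])
            ],
        )

    def validate_atlas(self) -> None:
        if not self.embryos:
            raise ConfigError("no embryos configured")
        if self.embryo_k > len(self.embryos):
            raise ConfigError(
                f"embryo_k={self.embryo_k} exceeds the {len(self.embryos)} configured embryos"
            )
        if self.reference_stack is None:
            raise ConfigError("reference_stack is required for the atlas build")
        missing = []
        for e in self.embryos:
            if len(e.channels) < 1:
                raise ConfigError(f"embryo {e.id} lists no channel stacks")
            if len(e.annotations) < 2:
                raise ConfigError(f"embryo {e.id} needs at least 2 user annotations")
            missing += [p for p in e.channels + e.annotations if not Path(p).exists()]
        for p in (self.reference_stack, self.reference_model):
            if p and not Path(p).exists():
                missing.append(p)
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    def validate_birthdate(self) -> None:
        if self.total_mask is None:
            raise ConfigError("total_mask is required for the birthdate build")
        if not self.photoconversions:
            raise ConfigError("at least one photoconversion mask is required")
        if self.acquisition_hpf is None:
            raise ConfigError("acquisition_time is required")
        missing = [
            p["mask"] for p in self.photoconversions + self.populations
            if not Path(p["mask"]).exists()
        ]
        if self.total_mask and not Path(self.total_mask).exists():
            missing.append(self.total_mask)
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def _provenance(config: PipelineConfig, extra: dict) -> dict:
    return {
        "atlasmaker_version": __version__,
        "seed": config.seed,
        "user_k": config.user_k,
        "embryo_k": config.embryo_k,
        "scales": list(config.scales),
        **extra,
    }


def run_atlas_build(config: PipelineConfig) -> Path:
    """Execute register -> segment -> consensus -> quantify.

    Writes, under ``config.output_dir``: per-embryo transforms and
    registered stacks, per-user masks, the label 3D-model, volume and
    axis-profile CSVs and ``provenance.json``.  Any stage failure halts
    with a stage-tagged error; partial outputs are preserved.
    """
    config.validate_atlas()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-reference"
    try:
        reference = read_stack(config.reference_stack, default_spacing=config.default_spacing)
        sig = config.signal_channel - 1

        stage = "register"
        registered: dict[str, list] = {}
        for e in config.embryos:
            stacks = [
                read_stack(c, default_spacing=config.default_spacing) for c in e.channels
            ]
            transform, trace = register_rigid(stacks[0], reference, config.registration)
            write_transform(transform, out / f"{e.id}_transform.txt")
            registered[e.id] = [
                apply_transform(s, transform, reference, "linear") for s in stacks
            ]
            log.info("registered %s (final similarity %.4f)", e.id, trace[-1])

        stage = "segment"
        per_embryo_masks: dict[str, list] = {}
        for e in config.embryos:
            signal_stack = registered[e.id][min(sig, len(registered[e.id]) - 1)]
            features = compute_features(signal_stack, config.scales)
            masks = []
            for u, ann_path in enumerate(e.annotations):
                ann = Annotation.from_dataframe(pd.read_csv(ann_path))
                clf = train_classifier(features, ann, seed=config.seed)
                mask = segment_volume(signal_stack, clf)
                write_mask(mask, out / f"{e.id}_user{u + 1}_mask.tif")
                masks.append(mask)
            per_embryo_masks[e.id] = masks

        stage = "outlier-users"
        n_users = min(len(m) for m in per_embryo_masks.values())
        flagged: set = set()
        if n_users >= 2 and len(config.embryos) >= 3:
            volumes = np.array(
                [
                    [mask_volume(per_embryo_masks[e.id][u]) for e in config.embryos]
                    for u in range(n_users)
                ]
            )
            table = UserVolumeTable.from_array(volumes)
            flagged, anova = flag_outlier_users(table)
            anova.to_csv(out / "user_anova.csv", index=False)
            if flagged:
                log.warning("outlier user classifiers flagged: %s", sorted(flagged))
                keep = [u for u in range(n_users) if f"u{u + 1}" not in flagged]
                if len(keep) >= 2:
                    per_embryo_masks = {
                        k: [v[u] for u in keep] for k, v in per_embryo_masks.items()
                    }

        stage = "consensus"
        model = build_label_model(
            [per_embryo_masks[e.id] for e in config.embryos],
            user_rule=config.user_k,
            embryo_k=config.embryo_k,
            embryo_ids=[e.id for e in config.embryos],
        )
        write_mask(model.mask, out / "label_model.tif")
        embryo_consensus = {
            e.id: threshold_consensus(
                average_masks(per_embryo_masks[e.id]),
                len(per_embryo_masks[e.id]) if config.user_k == "all" else int(config.user_k),
            )
            for e in config.embryos
        }

        stage = "quantify"
        vols = {k: mask_volume(v) for k, v in embryo_consensus.items()}
        model_vol = mask_volume(model.mask)
        var_df, mean_dev = variability_to_model(list(vols.values()), model_vol)
        var_df.insert(0, "embryo", list(vols.keys()))
        var_df.to_csv(out / "volumes.csv", index=False)
        ref_model = (
            read_mask(config.reference_model, default_spacing=config.default_spacing)
            if config.reference_model
            else model.mask
        )
        smoothing = config.smoothing
        for axis in config.axes:
            profile = axis_profile(model.mask, ref_model, axis)
            if smoothing not in (None, "none") and profile.valid.sum() >= 5:
                cfg = RegressionConfig(
                    bandwidth="cv" if smoothing == "cv" else float(smoothing)
                )
                profile = smooth_profile(profile, cfg)
            profile.to_dataframe().to_csv(out / f"profile_{axis}.csv", index=False)

        stage = "provenance"
        prov = _provenance(
            config,
            {
                "stage": "atlas",
                "embryos": [e.id for e in config.embryos],
                "flagged_users": sorted(flagged),
                "model_volume_um3": model_vol,
                "mean_deviation_pct": mean_dev,
                "registration": vars(config.registration),
            },
        )
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    except AtlasError as exc:
        raise AtlasError(f"[stage: {stage}] {exc}") from exc
    return out


def run_birthdate_build(config: PipelineConfig) -> Path:
    """Build the birthdate map and population fraction tables."""
    config.validate_birthdate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        total = read_mask(config.total_mask, default_spacing=config.default_spacing)
        convs = sorted(config.photoconversions, key=lambda p: p["time"])
        masks = [
            read_mask(p["mask"], default_spacing=config.default_spacing) for p in convs
        ]
        times = [p["time"] for p in convs]

        stage = "birthdate-map"
        bmap = build_birthdate_map(
            masks, total, times, config.acquisition_hpf, config.enforce_nesting
        )
        from .core import VolumeStack
        from .io import write_stack

        write_stack(
            VolumeStack(bmap.labels.astype(np.uint8), bmap.spacing),
            out / "birthdate_map.tif",
        )
        legend = pd.DataFrame(
            {"label": range(1, bmap.n_intervals + 1), "interval": bmap.interval_names()}
        )
        legend.to_csv(out / "birthdate_map_legend.csv", index=False)
        interval_growth_table(bmap).to_csv(out / "intervals.csv", index=False)

        stage = "populations"
        for p in config.populations:
            pop = read_mask(p["mask"], default_spacing=config.default_spacing)
            fractions = population_birthdates(pop, bmap, p["id"])
            fractions.to_dataframe(bmap.interval_names()).to_csv(
                out / f"fractions_{p['id']}.csv", index=False
            )

        stage = "provenance"
        prov = _provenance(
            config,
            {
                "stage": "birthdate",
                "times_hpf": times,
                "acquisition_hpf": config.acquisition_hpf,
                "enforce_nesting": config.enforce_nesting,
                "repaired_voxels": bmap.repaired_voxels,
            },
        )
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    except AtlasError as exc:
        raise AtlasError(f"[stage: {stage}] {exc}") from exc
    return out
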