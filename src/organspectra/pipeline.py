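"""Config-driven end-to-end orchestration of the analysis stages.

Stages (each can be toggled): simulate -> preprocess -> atlas -> variance
-> embedding -> train -> evaluate.  A single global seed deterministically
derives one sub-seed per stage; every stochastic stage refuses to run
unseeded.  ``run`` writes all stage outputs under the configured output
directory and returns a manifest recording seeds, output hashes and the
design-decision values in effect.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atlas import compute_atlas, export_atlas
from .classifier import (
    ArchitectureSpec,
    TrainingConfig,
    ensemble_predict,
    evaluate,
    lopo_validation_accuracy,
    run_lopo,
    split_train_test,
    table_classes,
)
from .embedding import EmbeddingConfig, embed
from .hsi_core import SpectraTable, build_spectra_table
from .lmm import bootstrap_decomposition_table, decompose_table
from .synthetic import (
    components_from_proportions,
    make_fingerprint_library,
    make_standardized_design,
    normalize_table,
    render_cube,
    simulate_spectra,
)

__all__ = ["PipelineConfig", "run", "derive_stage_seed"]

STAGES = ("simulate", "preprocess", "atlas", "variance", "embedding", "train", "evaluate")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int
    stages: tuple[str, ...] = STAGES
    spectra_csv: str | None = None  # existing table; otherwise simulate
    n_pigs: int = 8
    n_organs: int = 20
    n_positions: int = 2
    bootstrap_B: int = 50
    n_test_pigs: int = 2
    embedding_config: EmbeddingConfig | None = None
    embedding_max_rows: int = 600
    training: TrainingConfig = field(default_factory=TrainingConfig)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("stochastic stages refuse to run unseeded")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "training" in raw:
            raw["training"] = TrainingConfig(**raw["training"])
        if "architecture" in raw:
            raw["architecture"] = ArchitectureSpec(**raw["architecture"])
        if "embedding_config" in raw:
            raw["embedding_config"] = EmbeddingConfig(**raw["embedding_config"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate_inputs(self) -> None:
        if self.spectra_csv is not None and not Path(self.spectra_csv).exists():
            raise FileNotFoundError(f"spectra file not found: {self.spectra_csv}")
        if self.spectra_csv is None and "simulate" not in self.stages:
            raise ValueError("no spectra_csv given and the simulate stage is disabled")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write ``manifest.json``.

    A stage failure halts the run; the manifest written so far (with the
    failing stage named) is persisted before the exception propagates.
    """
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "design_decisions": {
            "convolution_padding": "valid",
            "batch_norm_before_elu": True,
            "lr_decay_applied": "per_epoch",
            "argmax_tie_break": "lowest_class_index",
            "median_spectrum_renormalized": True,
            "lmm_estimation": "REML",
            "fixed_term_cross_covariance": "split_equally",
        },
        "outputs": {},
    }

    def record(stage: str, outputs: dict, t0: float) -> None:
        entry = {"stage": stage, "seed": derive_stage_seed(config.seed, stage),
                 "seconds": round(time.time() - t0, 2), "status": "ok"}
        for name, path in outputs.items():
            manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
        manifest["stages"].append(entry)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    table: SpectraTable | None = None
    raw_table: SpectraTable | None = None
    lib = None
    current = None
    try:
        if "simulate" in config.stages:
            current, t0 = "simulate", time.time()
            seed = derive_stage_seed(config.seed, "simulate")
            lib = make_fingerprint_library(config.n_organs, seed=seed)
            comps = components_from_proportions(lib)
            design = make_standardized_design(
                config.n_pigs, organs=lib.organs, n_positions=config.n_positions
            )
            raw_table = simulate_spectra(design, lib, comps, seed=seed + 1)
            table = normalize_table(raw_table)
            raw_path = out / "spectra_raw.csv"
            norm_path = out / "spectra.csv"
            raw_table.to_csv(raw_path)
            table.to_csv(norm_path)
            record("simulate", {"spectra_raw": raw_path, "spectra": norm_path}, t0)
        elif config.spectra_csv:
            table = SpectraTable.read_csv(config.spectra_csv)
            raw_table = table

        if "preprocess" in config.stages:
            # round-trip QC: render a few spectra into cubes, re-extract them
            current, t0 = "preprocess", time.time()
            seed = derive_stage_seed(config.seed, "preprocess")
            from .hsi_core import MedianSpectrum

            bands = table.grid.band_columns
            errors = []
            for k in range(min(3, len(table))):
                row = table.df.iloc[k]
                med = MedianSpectrum(
                    values=row[bands].to_numpy(dtype=float),
                    pig_id=row["pig_id"], organ=row["organ"],
                    image_id=f'{row["image_id"]}_rt', position_id=row["position_id"],
                    angle=row["angle"], repetition=int(row["repetition"]),
                    n_pixels=1,
                )
                cube, ann = render_cube(med, (24, 24), pixel_noise_sd=1e-4, seed=seed + k)
                rt = build_spectra_table([cube], [ann])
                errors.append(float(np.abs(rt.band_matrix[0] - med.values).max()))
            qc_path = out / "preprocess_qc.json"
            qc_path.write_text(json.dumps({"roundtrip_linf": errors}))
            record("preprocess", {"preprocess_qc": qc_path}, t0)

        if "atlas" in config.stages:
            current, t0 = "atlas", time.time()
            atlas_dir = out / "atlas"
            export_atlas(compute_atlas(table), atlas_dir)
            record("atlas", {"atlas_index": atlas_dir / "index.json"}, t0)

        if "variance" in config.stages:
            current, t0 = "variance", time.time()
            seed = derive_stage_seed(config.seed, "variance")
            if config.bootstrap_B > 0:
                vd = bootstrap_decomposition_table(raw_table, B=config.bootstrap_B, seed=seed)
            else:
                vd = decompose_table(raw_table)
            var_path = out / "variance_decomposition.csv"
            vd.to_long_csv(var_path)
            med_path = out / "variance_medians.json"
            med_path.write_text(json.dumps(vd.medians(), indent=1))
            record("variance", {"variance": var_path, "variance_medians": med_path}, t0)

        if "embedding" in config.stages:
            current, t0 = "embedding", time.time()
            seed = derive_stage_seed(config.seed, "embedding")
            emb_cfg = config.embedding_config or EmbeddingConfig(seed=seed)
            sub = table
            if len(sub) > config.embedding_max_rows:
                step = int(np.ceil(len(sub) / config.embedding_max_rows))
                sub = sub.subset(sub.df.index % step == 0)
            result = embed(sub, emb_cfg)
            coords = sub.df[["pig_id", "organ"]].copy()
            coords[["tsne_1", "tsne_2"]] = result.coordinates
            emb_path = out / "embedding.csv"
            coords.to_csv(emb_path, index=False)
            record("embedding", {"embedding": emb_path}, t0)

        folds = None
        classes = None
        split = None
        if "train" in config.stages:
            current, t0 = "train", time.time()
            seed = derive_stage_seed(config.seed, "train")
            pigs = sorted(set(table.df["pig_id"]))
            organs_per_pig = table.df.groupby("pig_id")["organ"].agg(set).to_dict()
            split = split_train_test(
                pigs, pigs, organs_per_pig, n_test=config.n_test_pigs, seed=seed
            )
            classes = table_classes(table)
            train_tab = table.subset(table.df["pig_id"].isin(split.train_pigs))
            cfg = TrainingConfig(**{**asdict(config.training), "seed": seed})
            folds = run_lopo(train_tab, config.architecture, cfg, classes)
            train_path = out / "training.json"
            train_path.write_text(json.dumps({
                "train_pigs": list(split.train_pigs),
                "test_pigs": list(split.test_pigs),
                "lopo_validation_accuracy": lopo_validation_accuracy(folds),
                "fold_accuracies": {f.held_out_pig: f.accuracy for f in folds},
            }, indent=1))
            record("train", {"training": train_path}, t0)

        if "evaluate" in config.stages:
            current, t0 = "evaluate", time.time()
            if folds is None:
                raise ValueError("evaluate stage requires the train stage")
            from .classifier import _encode

            test_tab = table.subset(table.df["pig_id"].isin(split.test_pigs))
            Xte, yte = _encode(test_tab, classes)
            pred, _, _ = ensemble_predict([f.model for f in folds], Xte)
            report = evaluate(pred, yte, test_tab.df["pig_id"].to_numpy(), classes)
            rep_path = out / "report.json"
            rep_path.write_text(json.dumps({
                "micro_accuracy": report.micro_accuracy,
                "n_misclassified": report.n_misclassified,
                "n_annotations": report.n_annotations,
                "macro": report.macro,
            }, indent=1))
            conf_path = out / "confusion_mean.csv"
            report.confusion_mean.to_csv(conf_path)
            record("evaluate", {"report": rep_path, "confusion_mean": conf_path}, t0)
    except Exception:
        manifest["stages"].append({"stage": current, "status": "failed"})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    return manifest
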