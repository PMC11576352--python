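"""Pipeline orchestration with plain-file handoff between stages.

Each stage consumes the in-memory state left by the previous one (or the
declared input files) and writes its results as TSV/JSON into the output
directory, so every intermediate is inspectable and any stage can be run
stand-alone.  A manifest with a SHA-256 hash per written file is produced;
rerunning an identical config reproduces identical hashes because all
randomness flows from the recorded seed.

Configs are TOML; unknown keys are rejected by the pydantic schema so typos
fail loudly.  The resolved configuration is written next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as nio
from .compass import compass_match, extract_reference
from .multiblock import BlockDefinition, ConsensusPCA
from .oplsda import OPLSDA, cross_validate, labels_from_annotations
from .pca import PCA, refit_excluding
from .preprocess import PreprocessConfig, run_preprocess
from .simulate import CompoundSpec, SimConfig, builtin_library, simulate_dataset
from .stocsy import stocsy
from .types import AnnotationTable, SpectraMatrix
from .univariate import box_stats

logger = logging.getLogger("nmrprofile.pipeline")

STAGES = ("simulate", "preprocess", "pca", "oplsda", "stocsy", "multiblock",
          "compass", "boxstats")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputConfig(_Section):
    matrix: str = ""
    annotations: str = ""


class SimulateConfig(_Section):
    n_classes: int = 2
    n_per_class: list[int] = Field(default_factory=lambda: [20, 20])
    biomarkers: dict[str, list[float]] = Field(default_factory=dict)
    conc_range: dict[str, tuple[float, float]] = Field(default_factory=dict)
    default_conc_range: tuple[float, float] = (0.5, 2.0)
    shift_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    grid: tuple[float, float, int] = (10.0, 0.0, 1000)
    compounds: list[str] = Field(default_factory=list)  # names; empty = all


class PreprocessSection(_Section):
    excluded_regions: list[tuple[float, float]] = Field(default_factory=list)
    normalization: Literal["none", "total_area", "pqn"] = "none"
    area_target: float = 100.0
    scaling: Literal["none", "center", "uv", "pareto"] = "none"


class PcaSection(_Section):
    n_components: int = 2
    alpha: float = 0.05
    exclude: list[str] = Field(default_factory=list)


class OplsdaSection(_Section):
    n_orth: int = 1
    folds: int = 7
    test_matrix: str = ""


class StocsySection(_Section):
    driver: float = 1.33


class BlockSection(_Section):
    name: str
    ppm_hi: float
    ppm_lo: float
    scaling: Literal["none", "center", "uv", "pareto"] = "center"
    weight_rule: Literal["inverse_sqrt_p", "unit"] = "inverse_sqrt_p"


class MultiblockSection(_Section):
    n_components: int = 2
    blocks: list[BlockSection] = Field(default_factory=list)


class CompassSection(_Section):
    sample: str = ""
    window: tuple[float, float] = (1.36, 1.30)
    threshold: float = 0.8
    max_shift: int = 3


class BoxstatsSection(_Section):
    by_class: bool = False
    ppm: float | None = None


class RunConfig(_Section):
    """Top-level run configuration; one optional section per stage."""

    stages: list[str] = Field(default_factory=list)
    seed: int = 0
    input: InputConfig = Field(default_factory=InputConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    pca: PcaSection = Field(default_factory=PcaSection)
    oplsda: OplsdaSection = Field(default_factory=OplsdaSection)
    stocsy: StocsySection = Field(default_factory=StocsySection)
    multiblock: MultiblockSection = Field(default_factory=MultiblockSection)
    compass: CompassSection = Field(default_factory=CompassSection)
    boxstats: BoxstatsSection = Field(default_factory=BoxstatsSection)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.model_validate(data)


class PipelineState:
    """Carries the current matrix/annotations between stages."""

    def __init__(self) -> None:
        self.matrix: SpectraMatrix | None = None
        self.annotations: AnnotationTable | None = None

    def require_matrix(self, stage: str) -> SpectraMatrix:
        if self.matrix is None:
            raise RuntimeError(f"stage {stage!r} needs a spectral matrix; "
                               "run simulate first or declare [input]")
        return self.matrix

    def require_annotations(self, stage: str) -> AnnotationTable:
        if self.annotations is None:
            raise RuntimeError(f"stage {stage!r} needs annotations")
        return self.annotations


def stage_simulate(cfg: SimulateConfig, seed: int, out: Path,
                   state: PipelineState) -> list[Path]:
    lib = builtin_library()
    if cfg.compounds:
        by_name = {c.name: c for c in lib}
        unknown = [n for n in cfg.compounds if n not in by_name]
        if unknown:
            raise ValueError(f"unknown compounds: {unknown}; available: "
                             f"{sorted(by_name)}")
        compounds: list[CompoundSpec] = [by_name[n] for n in cfg.compounds]
    else:
        compounds = lib
    sim = simulate_dataset(SimConfig(
        compounds=compounds, n_classes=cfg.n_classes,
        n_per_class=list(cfg.n_per_class), biomarkers=dict(cfg.biomarkers),
        conc_range={k: tuple(v) for k, v in cfg.conc_range.items()},
        default_conc_range=tuple(cfg.default_conc_range),
        shift_jitter_sd=cfg.shift_jitter_sd, noise_sd=cfg.noise_sd,
        grid=tuple(cfg.grid), seed=seed))
    state.matrix, state.annotations = sim.matrix, sim.annotations
    files = [out / "matrix.tsv", out / "annotations.tsv", out / "truth.tsv"]
    nio.write_tsv_matrix(sim.matrix, files[0])
    nio.write_annotations(sim.annotations, files[1])
    sim.truth.rename_axis("sample_id").to_csv(files[2], sep="\t")
    return files


def stage_preprocess(cfg: PreprocessSection, out: Path,
                     state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("preprocess")
    res = run_preprocess(matrix, PreprocessConfig(
        excluded_regions=[tuple(r) for r in cfg.excluded_regions],
        normalization=cfg.normalization, area_target=cfg.area_target,
        scaling=cfg.scaling))
    state.matrix = res.matrix
    files = [out / "processed_matrix.tsv"]
    nio.write_tsv_matrix(res.matrix, files[0])
    prov = out / "preprocess_factors.tsv"
    with prov.open("w", encoding="utf-8") as fh:
        fh.write("record\tkey\tvalue\n")
        if res.dilution_factors is not None:
            for sid, f in zip(matrix.sample_ids, res.dilution_factors):
                fh.write(f"dilution_factor\t{sid}\t{float(f)!r}\n")
        if res.quotient_factors is not None:
            for sid, f in zip(matrix.sample_ids, res.quotient_factors):
                fh.write(f"quotient_factor\t{sid}\t{float(f)!r}\n")
        if res.centers is not None:
            for ppm, c in zip(res.matrix.ppm_grid, res.centers):
                fh.write(f"center\t{float(ppm)!r}\t{float(c)!r}\n")
        if res.scales is not None:
            for ppm, s in zip(res.matrix.ppm_grid, res.scales):
                fh.write(f"scale\t{float(ppm)!r}\t{float(s)!r}\n")
    files.append(prov)
    return files


def stage_pca(cfg: PcaSection, out: Path, state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("pca")
    if cfg.exclude:
        res, projected = refit_excluding(matrix, cfg.exclude,
                                         cfg.n_components)
        (out / "projected_excluded.tsv").write_text(
            projected.rename_axis("sample_id").to_csv(sep="\t"),
            encoding="utf-8")
    else:
        res = PCA(matrix, cfg.n_components).fit()
    files = [out / "scores.tsv", out / "loadings.tsv", out / "variance.tsv",
             out / "outliers.tsv"]
    res.scores.rename_axis("sample_id").to_csv(files[0], sep="\t")
    res.loadings.rename_axis("ppm").to_csv(files[1], sep="\t")
    with files[2].open("w", encoding="utf-8") as fh:
        fh.write("component\texplained_variance_ratio\n")
        for a, v in enumerate(res.explained_variance_ratio, start=1):
            fh.write(f"{a}\t{float(v)!r}\n")
    report = res.hotelling_outliers(cfg.alpha)
    with files[3].open("w", encoding="utf-8") as fh:
        fh.write(f"# alpha={cfg.alpha} limit={float(report.limit)!r}\n")
        fh.write("sample_id\tt2\tflagged\n")
        for sid, t2 in report.t2.items():
            fh.write(f"{sid}\t{float(t2)!r}\t{sid in set(report.flagged)}\n")
    if cfg.exclude:
        files.append(out / "projected_excluded.tsv")
    return files


def stage_oplsda(cfg: OplsdaSection, seed: int, out: Path,
                 state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("oplsda")
    ann = state.require_annotations("oplsda")
    labels = labels_from_annotations(matrix, ann)
    res = OPLSDA(matrix, labels, n_orth=cfg.n_orth).fit()
    res.q2 = cross_validate(matrix, labels, n_orth=cfg.n_orth,
                            folds=cfg.folds, seed=seed)
    files = [out / "oplsda_model.json", out / "oplsda_scores.tsv",
             out / "oplsda_loadings.tsv", out / "predictions.tsv"]
    model_doc = {
        "class_labels": list(res.class_labels),
        "n_orth": res.n_orth,
        "q": res.q, "y_mean": res.y_mean,
        "r2y": res.r2y, "r2x_pred": res.r2x_pred, "r2x_orth": res.r2x_orth,
        "q2": res.q2,
        "centers": res.centers.tolist(),
        "w": res.w.tolist(),
        "p_pred": res.p_pred.tolist(),
        "W_o": res.W_o.tolist(), "P_o": res.P_o.tolist(),
    }
    files[0].write_text(json.dumps(model_doc, indent=1, sort_keys=True),
                        encoding="utf-8")
    train_pred = res.predict(matrix)
    frame = train_pred.to_frame(matrix.sample_ids)
    frame.insert(0, "set", "train")
    if cfg.test_matrix:
        test = nio.read_tsv_matrix(cfg.test_matrix)
        test_pred = res.predict(test)
        tf = test_pred.to_frame(test.sample_ids)
        tf.insert(0, "set", "test")
        frame = pd.concat([frame, tf])
    frame.rename_axis("sample_id").to_csv(files[3], sep="\t")
    scores = train_pred.to_frame(matrix.sample_ids).drop(
        columns=["predicted_class", "y_hat"])
    scores.rename_axis("sample_id").to_csv(files[1], sep="\t")
    res.loading_decomposition().to_csv(files[2], sep="\t", index=False)
    return files


def stage_stocsy(cfg: StocsySection, out: Path,
                 state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("stocsy")
    res = stocsy(matrix, cfg.driver)
    f = out / "stocsy.tsv"
    res.to_frame().to_csv(f, sep="\t", index=False)
    return [f]


def stage_multiblock(cfg: MultiblockSection, out: Path,
                     state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("multiblock")
    if not cfg.blocks:
        raise ValueError("multiblock stage declared without blocks")
    blocks = [BlockDefinition(name=b.name, ppm_hi=b.ppm_hi, ppm_lo=b.ppm_lo,
                              scaling=b.scaling, weight_rule=b.weight_rule)
              for b in cfg.blocks]
    res = ConsensusPCA(matrix, blocks, cfg.n_components).fit()
    files = [out / "super_scores.tsv", out / "super_weights.tsv"]
    res.super_scores_frame().rename_axis("sample_id").to_csv(files[0],
                                                             sep="\t")
    res.super_weights_frame().rename_axis("block").to_csv(files[1], sep="\t")
    for b, block in enumerate(blocks):
        cols = [f"t{a + 1}" for a in range(cfg.n_components)]
        sf = out / f"block_{block.name}_scores.tsv"
        lf = out / f"block_{block.name}_loadings.tsv"
        pd.DataFrame(res.block_scores[b], index=matrix.sample_ids,
                     columns=cols).rename_axis("sample_id").to_csv(sf,
                                                                   sep="\t")
        grid = matrix.ppm_grid[
            (matrix.ppm_grid <= block.ppm_hi)
            & (matrix.ppm_grid >= block.ppm_lo)]
        pd.DataFrame(res.block_loadings[b], index=grid,
                     columns=cols).rename_axis("ppm").to_csv(lf, sep="\t")
        files += [sf, lf]
    return files


def stage_compass(cfg: CompassSection, out: Path,
                  state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("compass")
    if not cfg.sample:
        raise ValueError("compass stage needs a source sample id")
    pattern = extract_reference(matrix, cfg.sample, cfg.window[0],
                                cfg.window[1])
    result = compass_match(matrix, pattern, cfg.max_shift, cfg.threshold)
    files = [out / "compass.tsv", out / "compass_summary.json"]
    result.to_frame().rename_axis("sample_id").to_csv(files[0], sep="\t")
    files[1].write_text(json.dumps({
        "n_containing": result.n_containing,
        "threshold": result.threshold,
        "max_shift_points": result.max_shift_points,
        "ranking": result.ranking,
    }, indent=1), encoding="utf-8")
    return files


def stage_boxstats(cfg: BoxstatsSection, out: Path,
                   state: PipelineState) -> list[Path]:
    matrix = state.require_matrix("boxstats")
    grouping = "by_class" if cfg.by_class else "whole"
    ann = state.annotations if cfg.by_class else None
    stats = box_stats(matrix, ann, grouping)
    f = out / "boxstats.tsv"
    flat = stats.table.copy()
    flat.index = [f"{g}.{s}" for g, s in flat.index]
    flat.rename_axis("group.statistic").to_csv(f, sep="\t")
    return [f]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in order; return the manifest.

    The manifest maps every written file to its SHA-256 hash; with a fixed
    seed and identical inputs a rerun reproduces identical hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    state = PipelineState()
    if config.input.matrix:
        state.matrix = nio.read_tsv_matrix(config.input.matrix)
    if config.input.annotations:
        state.annotations = nio.read_annotations(config.input.annotations)

    written: list[Path] = []
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                written += stage_simulate(config.simulate, config.seed, out,
                                          state)
            elif stage == "preprocess":
                written += stage_preprocess(config.preprocess, out, state)
            elif stage == "pca":
                written += stage_pca(config.pca, out, state)
            elif stage == "oplsda":
                written += stage_oplsda(config.oplsda, config.seed, out,
                                        state)
            elif stage == "stocsy":
                written += stage_stocsy(config.stocsy, out, state)
            elif stage == "multiblock":
                written += stage_multiblock(config.multiblock, out, state)
            elif stage == "compass":
                written += stage_compass(config.compass, out, state)
            elif stage == "boxstats":
                written += stage_boxstats(config.boxstats, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    resolved = out / "resolved_config.json"
    resolved.write_text(config.model_dump_json(indent=1), encoding="utf-8")
    written.append(resolved)
    manifest = {"seed": config.seed,
                "files": {p.name: _sha256(p) for p in sorted(set(written))}}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True),
                             encoding="utf-8")
    return manifest
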