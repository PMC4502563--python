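"""End-to-end orchestration: simulate → quantify → compare.

One seeded run produces the full report bundle on synthetic data: a per-cell
measurement CSV (Golgi enrichment ratio and ER colocalization per cell), a
secretion-estimate CSV (per-experiment and pooled CM/CL fractions from the
simulated ELISA), a comparisons CSV (Tukey contrasts vs wild type, CMH odds
ratios with 95% CIs, Bonferroni significance calls) and a JSON summary with
per-genotype distribution statistics and record counts.

Each stage draws from its own RNG stream derived by hashing (master seed,
stage label), so adding or removing a stage never shifts another stage's
draws.  Every output file embeds the master seed and a hash of the
configuration in a leading ``#`` comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, imaging, scenes, secretion, stats
from .exceptions import ParameterError, PipelineStageError
from .phenotypes import (
    GenotypePhenotype,
    flpin_phenotypes,
    hek293t_phenotypes,
    hela_phenotypes,
)

__all__ = ["PipelineConfig", "ImagingConfig", "AssayConfig", "AnalysisConfig",
           "run_pipeline", "compare_tables", "default_config"]

logger = logging.getLogger(__name__)

_PHENOTYPE_SETS = {
    "flpin": flpin_phenotypes,
    "hek293t": hek293t_phenotypes,
    "hela": hela_phenotypes,
}


@dataclass(frozen=True)
class ImagingConfig:
    n_images: int = 2
    cells_per_image: int = 12
    image_shape: tuple[int, int] = (420, 420)
    noise: scenes.NoiseParams = field(default_factory=scenes.NoiseParams)
    render: scenes.RenderParams = field(default_factory=scenes.RenderParams)
    quant: imaging.QuantConfig = field(default_factory=imaging.QuantConfig)


@dataclass(frozen=True)
class AssayConfig:
    n_experiments: int = 3
    n_replicates: int = 2
    params: assays.AssayParams = field(default_factory=assays.AssayParams)
    western_params: assays.WesternParams = field(default_factory=assays.WesternParams)


@dataclass(frozen=True)
class AnalysisConfig:
    outlier_k: float = 3.0
    alpha: float = 0.05
    m_constructs: int = 11
    pseudo_n: int = 1000
    cmh_correction: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    phenotypes: dict[str, GenotypePhenotype]
    reference: str = "wt"
    seed: int = 0
    out_dir: Path = Path("clutraffic_out")
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.reference not in self.phenotypes:
            raise ParameterError(
                f"reference genotype {self.reference!r} not in phenotype table"
            )

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o))

        # out_dir does not affect the results, so it is excluded from the hash
        state = dataclasses.asdict(self)
        state.pop("out_dir", None)
        payload = json.dumps(state, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_config(seed: int = 0, out_dir: str | Path = "clutraffic_out") -> PipelineConfig:
    """Demo configuration: wild type plus the two ER-retained point mutants."""
    table = flpin_phenotypes()
    return PipelineConfig(phenotypes=table, seed=seed, out_dir=Path(out_dir))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML configuration file.

    A ``phenotype_set`` key ("flpin", "hek293t", "hela") selects a packaged
    table; explicit ``[phenotypes.<name>]`` sections override or extend it.
    """
    raw = tomllib.loads(Path(path).read_text())
    table: dict[str, GenotypePhenotype] = {}
    if "phenotype_set" in raw:
        table.update(_PHENOTYPE_SETS[raw["phenotype_set"]]())
    for name, kw in raw.get("phenotypes", {}).items():
        table[name] = GenotypePhenotype(name=name, **kw)
    if not table:
        table = flpin_phenotypes()

    img_raw = dict(raw.get("imaging", {}))
    noise = scenes.NoiseParams(**img_raw.pop("noise", {}))
    render = scenes.RenderParams(**img_raw.pop("render", {}))
    quant = imaging.QuantConfig(**img_raw.pop("quant", {}))
    if "image_shape" in img_raw:
        img_raw["image_shape"] = tuple(img_raw["image_shape"])
    img = ImagingConfig(noise=noise, render=render, quant=quant, **img_raw)

    assay_raw = dict(raw.get("assay", {}))
    aparams = assays.AssayParams(**assay_raw.pop("params", {}))
    wparams = assays.WesternParams(**assay_raw.pop("western_params", {}))
    assay = AssayConfig(params=aparams, western_params=wparams, **assay_raw)

    analysis = AnalysisConfig(**raw.get("analysis", {}))
    return PipelineConfig(
        phenotypes=table,
        reference=raw.get("reference", "wt"),
        seed=int(raw.get("seed", 0)),
        out_dir=Path(raw.get("out_dir", "clutraffic_out")),
        imaging=img,
        assay=assay,
        analysis=analysis,
    )


def stage_seed(master_seed: int, label: str) -> int:
    """Independent per-stage seed: hash of (master seed, stage label)."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# comparison layer shared by run_pipeline and the `compare` CLI command

def compare_tables(
    cells: pd.DataFrame,
    estimates: list[secretion.SecretionEstimate],
    reference: str,
    analysis: AnalysisConfig,
) -> tuple[pd.DataFrame, dict]:
    """Tukey contrasts on per-cell metrics and CMH on secretion estimates.

    Outlier removal is a single pooled pass per metric (mean and sd over all
    genotypes together), matching the pooled 3-sd rule.  Returns the
    comparisons table plus bookkeeping counts.
    """
    results: list[stats.ComparisonResult] = []
    counts: dict[str, int] = {}
    usable = cells[~cells["excluded"]] if len(cells) else cells

    for metric in ("golgi_ratio", "pearson_er"):
        if not len(usable):
            counts[f"outliers_removed_{metric}"] = 0
            continue
        sub = usable[["genotype", metric]].dropna()
        values = sub[metric].to_numpy(dtype=float)
        if values.size >= 3:
            _, removed = stats.remove_outliers(values, k=analysis.outlier_k)
        else:
            removed = np.array([], dtype=int)
        counts[f"outliers_removed_{metric}"] = int(removed.size)
        keep_mask = np.ones(values.size, dtype=bool)
        keep_mask[removed] = False
        sub = sub.iloc[keep_mask]
        groups = {
            g: v[metric].to_numpy(dtype=float)
            for g, v in sub.groupby("genotype")
            if len(v) >= 2
        }
        if reference not in groups or len(groups) < 2:
            continue
        res = stats.anova_tukey(groups, reference=reference)
        adjusted = stats.apply_bonferroni(
            res.contrasts, analysis.alpha, analysis.m_constructs
        )
        results.extend(dataclasses.replace(r, metric=metric) for r in adjusted)

    est_by_name = {e.genotype: e for e in estimates}
    if reference in est_by_name:
        ref_est = est_by_name[reference]
        cmh_results = []
        for name in sorted(est_by_name):
            if name == reference:
                continue
            strata = stats.build_strata(ref_est, est_by_name[name], analysis.pseudo_n)
            cmh_results.append(
                stats.cmh_test(
                    strata,
                    correction=analysis.cmh_correction,
                    genotype=name,
                    metric="cm_vs_cl",
                )
            )
        results.extend(
            stats.apply_bonferroni(cmh_results, analysis.alpha, analysis.m_constructs)
        )

    rows = [
        {
            "genotype": r.genotype,
            "metric": r.metric,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "or_mh": r.or_mh if r.or_mh is not None else np.nan,
            "ci_low": r.ci95[0] if r.ci95 else np.nan,
            "ci_high": r.ci95[1] if r.ci95 else np.nan,
            "significant": r.significant,
        }
        for r in results
    ]
    frame = pd.DataFrame(
        rows,
        columns=["genotype", "metric", "statistic", "p_raw", "p_adjusted",
                 "or_mh", "ci_low", "ci_high", "significant"],
    )
    return frame, counts


# ---------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path, header_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        frame.to_csv(fh, index=False)


@dataclass
class PipelineBundle:
    paths: dict[str, Path]
    summary: dict


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Run simulate → quantify → compare and write the report bundle.

    Deterministic given (config, seed).  Any stage failure aborts the run
    with the stage name and removes partially written outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"# clutraffic seed={config.seed} config_hash={chash}"
    written: list[Path] = []
    phenos = list(config.phenotypes.values())

    def _run_stage(stage, fn, context=""):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineStageError(stage, context or "no context", exc) from exc

    # --- imaging ---
    def _imaging():
        records = []
        icfg = config.imaging
        for i in range(icfg.n_images):
            scene = scenes.make_scene(
                n_cells=icfg.cells_per_image,
                phenotypes=phenos,
                image_shape=icfg.image_shape,
                noise=icfg.noise,
                seed=stage_seed(config.seed, f"image{i}"),
                render=icfg.render,
            )
            records.extend(
                imaging.quantify_image(scene, config=icfg.quant, image_id=f"img{i:03d}")
            )
        return imaging.measurements_to_frame(records)

    cells = _run_stage("imaging", _imaging)
    logger.info("imaging: %d cells measured, %d excluded",
                len(cells), int(cells["excluded"].sum()) if len(cells) else 0)

    # --- secretion (ELISA) ---
    def _secretion():
        table = assays.simulate_assay(
            phenos,
            n_experiments=config.assay.n_experiments,
            n_replicates=config.assay.n_replicates,
            params=config.assay.params,
            seed=stage_seed(config.seed, "elisa"),
        )
        corrected = secretion.subtract_matrix_background(table)
        normalized = secretion.normalize_by_tgfb(corrected)
        return secretion.compartment_fractions(normalized)

    estimates = _run_stage("secretion", _secretion)
    logger.info("secretion: %d genotypes estimated", len(estimates))

    # --- western ---
    def _western():
        table = assays.simulate_western(
            phenos,
            n_experiments=config.assay.n_experiments,
            params=config.assay.western_params,
            seed=stage_seed(config.seed, "western"),
        )
        return secretion.western_fractions(table, wt_label=config.reference)

    western_est, western_rescaled = _run_stage("western", _western)

    # --- comparisons ---
    comparisons, counts = _run_stage(
        "comparisons",
        lambda: compare_tables(cells, estimates, config.reference, config.analysis),
    )

    # --- write bundle ---
    paths = {
        "cells": out_dir / "cells.csv",
        "secretion": out_dir / "secretion_estimates.csv",
        "western": out_dir / "western_rescaled.csv",
        "comparisons": out_dir / "comparisons.csv",
        "summary": out_dir / "summary.json",
    }

    def _write_all():
        _write_csv(cells, paths["cells"], header)
        written.append(paths["cells"])
        _write_csv(secretion.estimates_to_frame(estimates), paths["secretion"], header)
        written.append(paths["secretion"])
        _write_csv(western_rescaled, paths["western"], header)
        written.append(paths["western"])
        _write_csv(comparisons, paths["comparisons"], header)
        written.append(paths["comparisons"])

        usable = cells[~cells["excluded"]] if len(cells) else cells
        per_genotype = {}
        for genotype, sub in usable.groupby("genotype"):
            entry = {"n_cells": int(len(sub))}
            for metric in ("golgi_ratio", "pearson_er"):
                vals = sub[metric].dropna()
                if len(vals):
                    entry[metric] = {
                        "median": float(vals.median()),
                        "q1": float(vals.quantile(0.25)),
                        "q3": float(vals.quantile(0.75)),
                    }
            per_genotype[genotype] = entry
        summary = {
            "seed": config.seed,
            "config_hash": chash,
            "n_cells_measured": int(len(cells)),
            "n_cells_excluded": int(cells["excluded"].sum()) if len(cells) else 0,
            **counts,
            "imaging_by_genotype": per_genotype,
            "secretion_proportions": {
                e.genotype: {
                    "cm_fraction": e.pooled_cm_fraction,
                    "cl_fraction": 1.0 - e.pooled_cm_fraction,
                    "n_experiments": e.n_experiments,
                }
                for e in estimates
            },
            "western_proportions": {
                e.genotype: {"cm_fraction": e.pooled_cm_fraction}
                for e in western_est
            },
            "significant": [
                {"genotype": r.genotype, "metric": r.metric}
                for r in comparisons.itertuples()
                if r.significant
            ],
        }
        paths["summary"].write_text(json.dumps(summary, indent=1))
        written.append(paths["summary"])
        return summary

    summary = _run_stage("report", _write_all)
    return PipelineBundle(paths=paths, summary=summary)
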