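"""Secreted-vs-intracellular clusterin fractions from ELISA and western data.

The correction chain for ELISA tables follows the assay protocol: the
immunoreactive matrix background (the mean response of nontransfected-cell
wells, pooled across experiments) is subtracted from every sample well;
concentrations are then normalized by the TGF-β1 column (division by each
record's normalizer relative to the grand-mean normalizer, which preserves
units); finally duplicates are averaged per (genotype, experiment,
compartment) and the conditioned-medium share ``CM/(CM+CL)`` is computed per
experiment and pooled as a ratio of summed amounts.

Western tables are first normalized lane-wise by the α-tubulin loading
control; fractions then follow the same arithmetic, and intensities are also
reported log2-rescaled against wild type per compartment and experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    IncompletePairError,
    MissingControlError,
    ReferenceError_,
)
from .phenotypes import NONTRANSFECTED

__all__ = [
    "SecretionEstimate",
    "subtract_matrix_background",
    "normalize_by_tgfb",
    "compartment_fractions",
    "western_fractions",
    "estimates_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerExperiment:
    experiment_id: int
    cm_amount: float
    cl_amount: float

    @property
    def cm_fraction(self) -> float:
        return self.cm_amount / (self.cm_amount + self.cl_amount)


@dataclass(frozen=True)
class SecretionEstimate:
    """Per-genotype CM/CL amounts per experiment plus the pooled fraction."""

    genotype: str
    per_experiment: list[PerExperiment]

    @property
    def n_experiments(self) -> int:
        return len(self.per_experiment)

    @property
    def pooled_cm_fraction(self) -> float:
        cm = sum(p.cm_amount for p in self.per_experiment)
        cl = sum(p.cl_amount for p in self.per_experiment)
        return cm / (cm + cl)


def subtract_matrix_background(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract the pooled nontransfected mean from every sample well.

    Control rows are removed from the output; corrected concentrations below
    zero are clamped to zero with a logged warning.
    """
    controls = table["genotype"] == NONTRANSFECTED
    if not controls.any():
        raise MissingControlError("no nontransfected control records in table")
    background = float(table.loc[controls, "concentration"].mean())
    out = table.loc[~controls].copy()
    corrected = out["concentration"] - background
    n_neg = int((corrected < 0).sum())
    if n_neg:
        logger.warning(
            "clamped %d corrected concentrations below 0 (background %.4g)",
            n_neg,
            background,
        )
    out["concentration"] = corrected.clip(lower=0.0)
    return out.reset_index(drop=True)


def normalize_by_tgfb(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each concentration by its relative TGF-β1 normalizer.

    Each record's concentration is divided by ``normalizer / mean(normalizer)``
    so that units are preserved; applied to all records (both compartments).
    """
    bad = table["normalizer"] <= 0
    if bad.any():
        idx = table.index[bad][0]
        raise DataError(f"non-positive normalizer in record {idx}: {table.loc[idx].to_dict()}")
    out = table.copy()
    grand_mean = float(table["normalizer"].mean())
    out["concentration"] = table["concentration"] / (table["normalizer"] / grand_mean)
    return out


def compartment_fractions(table: pd.DataFrame) -> list[SecretionEstimate]:
    """Average replicates and compute CM shares per experiment and pooled.

    Expects an already corrected and normalized table; every
    (genotype, experiment) must carry both compartments.
    """
    means = (
        table.groupby(["genotype", "experiment_id", "compartment"], sort=True)[
            "concentration"
        ]
        .mean()
        .unstack("compartment")
    )
    missing = means.isna().any(axis=1) if not means.empty else pd.Series(dtype=bool)
    for col in ("CM", "CL"):
        if col not in means.columns:
            raise IncompletePairError(f"compartment {col} absent from table")
    if missing.any():
        key = means.index[missing.to_numpy()][0]
        raise IncompletePairError(f"missing compartment for (genotype, experiment) {key}")

    estimates = []
    for genotype, sub in means.groupby(level="genotype", sort=True):
        per_exp = [
            PerExperiment(int(eid), float(row["CM"]), float(row["CL"]))
            for (_, eid), row in sub.iterrows()
        ]
        estimates.append(SecretionEstimate(str(genotype), per_exp))
    return estimates


def western_fractions(
    table: pd.DataFrame, wt_label: str = "wt"
) -> tuple[list[SecretionEstimate], pd.DataFrame]:
    """Tubulin-normalize band intensities, then fractions and log2-vs-wt.

    Returns ``(estimates, rescaled)`` where ``rescaled`` has one row per
    record with ``log2_vs_wt = log2(intensity' / wt intensity')`` computed per
    (experiment, compartment); wild type maps to 0 exactly.
    """
    if (table["tubulin_intensity"] <= 0).any():
        raise DataError("tubulin_intensity must be strictly positive")
    if not (table["genotype"] == wt_label).any():
        raise ReferenceError_(f"reference genotype {wt_label!r} absent from western table")

    norm = table.copy()
    norm["intensity"] = norm["band_intensity"] / norm["tubulin_intensity"]

    as_assay = norm.rename(columns={"intensity": "concentration"})
    as_assay["replicate"] = 1
    estimates = compartment_fractions(
        as_assay[["experiment_id", "genotype", "compartment", "replicate", "concentration"]]
    )

    wt = (
        norm[norm["genotype"] == wt_label]
        .set_index(["experiment_id", "compartment"])["intensity"]
        .rename("wt_intensity")
    )
    rescaled = norm.join(wt, on=["experiment_id", "compartment"])
    if rescaled["wt_intensity"].isna().any():
        raise ReferenceError_("wild-type lane missing for some (experiment, compartment)")
    with np.errstate(divide="ignore"):
        rescaled["log2_vs_wt"] = np.log2(rescaled["intensity"] / rescaled["wt_intensity"])
    rescaled.loc[rescaled["genotype"] == wt_label, "log2_vs_wt"] = 0.0
    return estimates, rescaled[
        ["experiment_id", "genotype", "compartment", "intensity", "log2_vs_wt"]
    ]


def estimates_to_frame(estimates: list[SecretionEstimate]) -> pd.DataFrame:
    """Long-format table: per-experiment rows plus one pooled row per genotype."""
    rows = []
    for est in estimates:
        for p in est.per_experiment:
            rows.append(
                {
                    "genotype": est.genotype,
                    "experiment_id": p.experiment_id,
                    "cm_amount": p.cm_amount,
                    "cl_amount": p.cl_amount,
                    "cm_fraction": p.cm_fraction,
                    "pooled": False,
                }
            )
        rows.append(
            {
                "genotype": est.genotype,
                "experiment_id": -1,
                "cm_amount": sum(p.cm_amount for p in est.per_experiment),
                "cl_amount": sum(p.cl_amount for p in est.per_experiment),
                "cm_fraction": est.pooled_cm_fraction,
                "pooled": True,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["genotype", "experiment_id", "cm_amount", "cl_amount", "cm_fraction", "pooled"],
    )
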