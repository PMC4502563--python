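"""Synthetic ELISA and western-blot tables with known secreted fractions.

The ELISA model mirrors the design of the secretion experiments: per
mutation, three independent experiments with all undiluted wells run in
duplicate, conditioned medium (CM) and cell lysate (CL) measured for every
construct plus nontransfected control wells that carry only the
immunoreactive matrix background, and a TGF-β1 column used downstream for
normalization.

For experiment *e* a total clusterin amount ``T_e`` is drawn log-normally
around ``total_clu_mean`` with coefficient of variation
``between_experiment_cv``; the construct with true secreted fraction ``f``
splits it as ``CM = f·T_e`` and ``CL = (1−f)·T_e``.  An observed well is::

    true_level * (normalizer_e / normalizer_mean) * (1 + replicate noise)
        + matrix background draw

so the multiplicative technical factor is exactly what TGF-β1 normalization
removes, and the additive background is what the nontransfected average
subtracts.  All draws come from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .phenotypes import NONTRANSFECTED, GenotypePhenotype

__all__ = [
    "AssayParams",
    "WesternParams",
    "simulate_assay",
    "simulate_western",
    "ASSAY_COLUMNS",
    "WESTERN_COLUMNS",
]

ASSAY_COLUMNS = [
    "experiment_id",
    "genotype",
    "compartment",
    "replicate",
    "concentration",
    "normalizer",
]
WESTERN_COLUMNS = [
    "experiment_id",
    "genotype",
    "compartment",
    "band_intensity",
    "tubulin_intensity",
]


def _check_cv(name: str, v: float) -> None:
    if not np.isfinite(v) or v < 0:
        raise ParameterError(f"{name} must be a finite CV >= 0, got {v!r}")


@dataclass(frozen=True)
class AssayParams:
    """ELISA simulation parameters (concentrations in ng/ml)."""

    total_clu_mean: float = 100.0
    between_experiment_cv: float = 0.2
    replicate_cv: float = 0.05
    matrix_background_mean: float = 2.0
    normalizer_cv: float = 0.1
    matrix_background_cv: float = 0.3
    normalizer_mean: float = 500.0

    def __post_init__(self) -> None:
        if self.total_clu_mean <= 0 or self.normalizer_mean <= 0:
            raise ParameterError("means must be > 0")
        if self.matrix_background_mean < 0:
            raise ParameterError("matrix_background_mean must be >= 0")
        for name in ("between_experiment_cv", "replicate_cv", "normalizer_cv", "matrix_background_cv"):
            _check_cv(name, getattr(self, name))


@dataclass(frozen=True)
class WesternParams:
    """Western-blot simulation parameters (band intensities, arbitrary units)."""

    total_band_mean: float = 1000.0
    between_experiment_cv: float = 0.2
    band_cv: float = 0.05
    tubulin_mean: float = 500.0
    tubulin_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.total_band_mean <= 0 or self.tubulin_mean <= 0:
            raise ParameterError("means must be > 0")
        for name in ("between_experiment_cv", "band_cv", "tubulin_cv"):
            _check_cv(name, getattr(self, name))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv == 0 or mean == 0:
        return np.full(size if size is not None else (), float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def simulate_assay(
    phenotypes: list[GenotypePhenotype],
    n_experiments: int = 3,
    n_replicates: int = 2,
    params: AssayParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format ELISA table (one row per well).

    Every experiment contains CM and CL wells in ``n_replicates`` for each
    phenotype plus nontransfected control wells carrying only the matrix
    background.  Deterministic given (inputs, seed).
    """
    if n_experiments < 1:
        raise ParameterError(f"n_experiments must be >= 1, got {n_experiments}")
    if n_replicates < 1:
        raise ParameterError(f"n_replicates must be >= 1, got {n_replicates}")
    if not phenotypes:
        raise ParameterError("phenotypes must be non-empty")
    params = params or AssayParams()
    rng = np.random.default_rng(seed)

    rows = []
    for e in range(1, n_experiments + 1):
        total = float(_lognormal(rng, params.total_clu_mean, params.between_experiment_cv))
        normalizer = float(_lognormal(rng, params.normalizer_mean, params.normalizer_cv))
        tech = normalizer / params.normalizer_mean
        for pheno in phenotypes:
            levels = {
                "CM": pheno.true_secreted_fraction * total,
                "CL": (1.0 - pheno.true_secreted_fraction) * total,
            }
            for compartment, true_level in levels.items():
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, params.replicate_cv) if params.replicate_cv > 0 else 0.0
                    bg = float(
                        _lognormal(rng, params.matrix_background_mean, params.matrix_background_cv)
                    )
                    conc = max(true_level * tech * (1.0 + noise) + bg, 0.0)
                    rows.append((e, pheno.name, compartment, rep, conc, normalizer))
        for compartment in ("CM", "CL"):
            for rep in range(1, n_replicates + 1):
                bg = float(
                    _lognormal(rng, params.matrix_background_mean, params.matrix_background_cv)
                )
                rows.append((e, NONTRANSFECTED, compartment, rep, bg, normalizer))
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def simulate_western(
    phenotypes: list[GenotypePhenotype],
    n_experiments: int = 3,
    params: WesternParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate western band intensities: one CM and one CL lane per
    (experiment, genotype), each with an α-tubulin loading-control band."""
    if n_experiments < 1:
        raise ParameterError(f"n_experiments must be >= 1, got {n_experiments}")
    if not phenotypes:
        raise ParameterError("phenotypes must be non-empty")
    params = params or WesternParams()
    rng = np.random.default_rng(seed)

    rows = []
    for e in range(1, n_experiments + 1):
        total = float(_lognormal(rng, params.total_band_mean, params.between_experiment_cv))
        for pheno in phenotypes:
            levels = {
                "CM": pheno.true_secreted_fraction * total,
                "CL": (1.0 - pheno.true_secreted_fraction) * total,
            }
            for compartment, true_level in levels.items():
                noise = rng.normal(0.0, params.band_cv) if params.band_cv > 0 else 0.0
                band = max(true_level * (1.0 + noise), 0.0)
                tubulin = float(_lognormal(rng, params.tubulin_mean, params.tubulin_cv))
                rows.append((e, pheno.name, compartment, band, tubulin))
    return pd.DataFrame(rows, columns=WESTERN_COLUMNS)
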