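"""Genotype-level trafficking phenotypes.

A :class:`GenotypePhenotype` collapses a construct's behaviour onto four
axes that drive the synthetic generators:

* ``golgi_enrichment`` — reporter intensity in the Golgi relative to the ER.
  Wild-type secreted clusterin accumulates strongly in the Golgi; the
  ER-retained β-chain mutants lose this accumulation (multiplier ≈ 1).
* ``er_retention`` — reporter intensity in the ER relative to the diffuse
  cytoplasmic level.  High for retained mutants.
* ``vesicle_density`` — expected number of bright post-Golgi puncta per cell
  (endosome-like vesicles seen for wild type).
* ``true_secreted_fraction`` — fraction of total clusterin exported to the
  conditioned medium (CM) rather than remaining in the cell lysate (CL).

The packaged tables carry the fractions measured by ELISA in HEK Flp-In and
HEK293T cells and imaging phenotypes qualitatively matching the HeLa
micrographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ParameterError

__all__ = [
    "GenotypePhenotype",
    "flpin_phenotypes",
    "hek293t_phenotypes",
    "hela_phenotypes",
]

#: Genotype label reserved for mock-transfected matrix-background wells.
NONTRANSFECTED = "nontransfected"


@dataclass(frozen=True)
class GenotypePhenotype:
    """Ground-truth trafficking behaviour of one construct."""

    name: str
    golgi_enrichment: float
    er_retention: float
    vesicle_density: float
    true_secreted_fraction: float

    def __post_init__(self) -> None:
        for field in ("golgi_enrichment", "er_retention", "vesicle_density"):
            v = getattr(self, field)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{field} must be finite and >= 0, got {v!r}")
        f = self.true_secreted_fraction
        if not (0.0 <= f <= 1.0):
            raise ParameterError(f"true_secreted_fraction must be in [0, 1], got {f!r}")
        if self.name == NONTRANSFECTED:
            raise ParameterError(f"{NONTRANSFECTED!r} is reserved for control wells")


# Imaging axes: wild type shows strong perinuclear Golgi accumulation, modest
# ER signal and cytoplasmic vesicles; the three β-chain mutants lose Golgi
# accumulation and sit almost exclusively in the ER.
_WT_IMAGING = dict(golgi_enrichment=8.0, er_retention=1.5, vesicle_density=8.0)
_RETAINED_IMAGING = dict(golgi_enrichment=1.0, er_retention=6.0, vesicle_density=0.0)


def flpin_phenotypes() -> dict[str, GenotypePhenotype]:
    """Constructs assayed in isogenic HEK Flp-In cells (ELISA fractions)."""
    return {
        "wt": GenotypePhenotype("wt", **_WT_IMAGING, true_secreted_fraction=0.91),
        "p.R338W": GenotypePhenotype(
            "p.R338W", **_RETAINED_IMAGING, true_secreted_fraction=0.68
        ),
        "p.I360N": GenotypePhenotype(
            "p.I360N", **_RETAINED_IMAGING, true_secreted_fraction=0.15
        ),
    }


def hek293t_phenotypes() -> dict[str, GenotypePhenotype]:
    """Constructs assayed in HEK293T cells (ELISA fractions)."""
    return {
        "wt": GenotypePhenotype("wt", **_WT_IMAGING, true_secreted_fraction=0.766),
        "p.R338W": GenotypePhenotype(
            "p.R338W", **_RETAINED_IMAGING, true_secreted_fraction=0.528
        ),
        "p.I360N": GenotypePhenotype(
            "p.I360N", **_RETAINED_IMAGING, true_secreted_fraction=0.123
        ),
    }


def hela_phenotypes() -> dict[str, GenotypePhenotype]:
    """Constructs imaged in HeLa cells.

    p.I303NfsX13 carries a premature stop and was never measured by ELISA
    (the truncated protein lacks the antibody epitope); its secreted fraction
    here is a nominal 0.05 used only to round out the simulation table.
    """
    table = flpin_phenotypes()
    table["p.I303NfsX13"] = GenotypePhenotype(
        "p.I303NfsX13", **_RETAINED_IMAGING, true_secreted_fraction=0.05
    )
    return table
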