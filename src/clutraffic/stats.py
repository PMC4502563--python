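"""Group statistics connecting per-cell and per-well measurements.

The layer mirrors the analysis applied to the imaging and secretion data:

* single-pass removal of extreme outliers (|x − mean| > 3 sd, computed once
  on the pooled metric);
* one-way ANOVA with Tukey HSD contrasts (Tukey–Kramer for unbalanced
  groups) against the wild-type reference;
* Bonferroni thresholding over the number of constructs tested
  (α/m; 0.05/11 ≈ 0.0045);
* the Cochran–Mantel–Haenszel test over experiment strata with the
  Mantel–Haenszel common odds ratio and its Robins–Breslow–Greenland 95% CI.

CM/CL amounts are continuous; :func:`build_strata` converts each genotype's
per-experiment amounts into pseudo-count 2×2 tables (each genotype row
rescaled to ``pseudo_n`` and rounded by largest remainder) so the CMH
machinery applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable as _SMStratifiedTable
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import ParameterError, StratificationError, UndefinedORError
from .secretion import SecretionEstimate

__all__ = [
    "ComparisonResult",
    "StratifiedTable",
    "AnovaTukeyResult",
    "remove_outliers",
    "anova_tukey",
    "bonferroni_threshold",
    "apply_bonferroni",
    "build_strata",
    "cmh_test",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One genotype-vs-reference comparison for one metric."""

    genotype: str
    metric: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    or_mh: float | None = None
    ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class AnovaTukeyResult:
    anova_f: float
    anova_p: float
    contrasts: list[ComparisonResult] = field(default_factory=list)


@dataclass(frozen=True)
class StratifiedTable:
    """2×2 tables (rows: reference, test; cols: CM, CL) per experiment."""

    strata: list[np.ndarray]
    experiment_ids: list[int]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ParameterError("at least one stratum required")
        for t in self.strata:
            if t.shape != (2, 2) or (t < 0).any() or t.sum() <= 0:
                raise ParameterError(f"invalid 2x2 stratum:\n{t}")


def remove_outliers(values, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 3-sd outlier rule on the full list.

    Mean and sd are computed once on all values; entries farther than
    ``k`` sd from the mean are removed.  Returns (kept values, removed
    indices).  A zero sd removes nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ParameterError(f"need at least 3 values, got {x.size}")
    m, s = x.mean(), x.std(ddof=1)
    if s == 0:
        return x.copy(), np.array([], dtype=int)
    removed = np.flatnonzero(np.abs(x - m) > k * s)
    kept = np.delete(x, removed)
    return kept, removed


def anova_tukey(
    groups: dict[str, "np.ndarray | list[float]"],
    reference: str | None = None,
    threshold: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD contrasts.

    With ``reference`` set, only contrasts against that group are returned
    (labelled by the other genotype); with ``reference=None`` all pairwise
    contrasts are returned (labelled ``"a|b"``).  Tukey p-values are already
    family-adjusted; ``significant`` compares them to ``threshold``.
    """
    if reference is not None and reference not in groups:
        raise ParameterError(f"reference group {reference!r} missing")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 values")
    if len(arrays) < 2:
        return AnovaTukeyResult(anova_f=float("nan"), anova_p=float("nan"))

    endog = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[g] * v.size for g, v in arrays.items()])

    def contrast_name(a: str, b: str) -> str | None:
        if reference is None:
            return f"{a}|{b}"
        if a == reference:
            return b
        if b == reference:
            return a
        return None

    if np.ptp(endog) == 0:
        # zero variance everywhere: F undefined, nothing can be significant
        contrasts = [
            ComparisonResult(name, "", 0.0, 1.0, 1.0, False)
            for a, b in combinations(sorted(arrays), 2)
            if (name := contrast_name(a, b)) is not None
        ]
        return AnovaTukeyResult(float("nan"), float("nan"), contrasts)

    f_stat, f_p = sps.f_oneway(*arrays.values())
    tukey = pairwise_tukeyhsd(endog, labels, alpha=threshold)
    order = list(tukey.groupsunique)
    contrasts = []
    for (ia, ib), diff, p in zip(
        combinations(range(len(order)), 2), tukey.meandiffs, tukey.pvalues
    ):
        name = contrast_name(order[ia], order[ib])
        if name is None:
            continue
        p = float(p)
        contrasts.append(
            ComparisonResult(
                genotype=name,
                metric="",
                statistic=float(diff),
                p_raw=p,
                p_adjusted=p,
                significant=bool(p < threshold),
            )
        )
    return AnovaTukeyResult(float(f_stat), float(f_p), contrasts)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold α/m."""
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    return alpha / m


def apply_bonferroni(
    results: list[ComparisonResult], alpha: float, m: int
) -> list[ComparisonResult]:
    """Adjust p-values for ``m`` constructs; significant ⇔ p_raw < α/m."""
    thr = bonferroni_threshold(alpha, m)
    return [
        replace(
            r,
            p_adjusted=min(1.0, r.p_raw * m),
            significant=bool(r.p_raw < thr),
        )
        for r in results
    ]


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment: floors, then remaining units by largest
    fractional part (ties broken by lower index)."""
    quotas = np.asarray(fractions, dtype=float) * total
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def build_strata(
    reference: SecretionEstimate,
    test: SecretionEstimate,
    pseudo_n: int = 1000,
) -> StratifiedTable:
    """Pseudo-count 2×2 tables from two genotypes' per-experiment amounts.

    Each genotype's (CM, CL) amounts are rescaled so the row sums to
    ``pseudo_n`` exactly (largest-remainder rounding); strata are experiments.
    """
    if pseudo_n < 2:
        raise ParameterError(f"pseudo_n must be >= 2, got {pseudo_n}")
    ref_by_exp = {p.experiment_id: p for p in reference.per_experiment}
    test_by_exp = {p.experiment_id: p for p in test.per_experiment}
    if set(ref_by_exp) != set(test_by_exp):
        raise StratificationError(
            f"experiment ids differ: {sorted(ref_by_exp)} vs {sorted(test_by_exp)}"
        )
    strata, ids = [], []
    for eid in sorted(ref_by_exp):
        rows = []
        for p in (ref_by_exp[eid], test_by_exp[eid]):
            total = p.cm_amount + p.cl_amount
            if total <= 0:
                raise StratificationError(f"experiment {eid}: zero total amount")
            rows.append(
                _largest_remainder(
                    np.array([p.cm_amount, p.cl_amount]) / total, pseudo_n
                )
            )
        strata.append(np.array(rows, dtype=int))
        ids.append(eid)
    return StratifiedTable(strata=strata, experiment_ids=ids)


def cmh_test(
    strata: StratifiedTable,
    correction: bool = False,
    genotype: str = "",
    metric: str = "cm_vs_cl",
    threshold: float = 0.05,
) -> ComparisonResult:
    """Cochran–Mantel–Haenszel test across experiment strata.

    The common odds ratio is reported in the *test-vs-reference* orientation
    (odds of a CM count for the test genotype relative to the reference), so
    an ER-retained mutant compared against wild type yields an OR < 1.  The
    95% CI uses the Robins–Breslow–Greenland variance.  Swapping the two
    genotype rows inverts the OR exactly.
    """
    tables = [t[::-1].copy() for t in strata.strata]  # test row first
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in tables)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in tables)
    if num == 0 and den == 0:
        raise UndefinedORError("every stratum has a zero margin; OR undefined")

    st = _SMStratifiedTable([np.asarray(t, dtype=np.float64) for t in tables])
    res = st.test_null_odds(correction=correction)
    or_mh = float(st.oddsratio_pooled)
    with np.errstate(divide="ignore", invalid="ignore"):
        lcb, ucb = st.oddsratio_pooled_confint(alpha=0.05)
    p = float(res.pvalue)
    return ComparisonResult(
        genotype=genotype,
        metric=metric,
        statistic=float(res.statistic),
        p_raw=p,
        p_adjusted=p,
        significant=bool(p < threshold),
        or_mh=or_mh,
        ci95=(float(lcb), float(ucb)),
    )
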