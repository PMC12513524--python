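"""Inter-rater reliability statistics for SLIEX scores.

When several observers score the same set of interventions independently,
three complementary statistics describe how well they agree:

* **Cohen's kappa** — chance-corrected agreement between two raters on
  categorical (integer) scores, with its large-sample standard error.  A
  pair of raters who each assign a single identical score throughout has no
  chance-corrected agreement to estimate; such cells are flagged as
  *constant* (100% observed agreement) rather than reported as a number.
* **Intraclass correlation (ICC)** — reliability of the scores treated as
  measurements, from the two-way ANOVA decomposition of the items x raters
  matrix.  The default model is ICC(2,1): two-way random effects, absolute
  agreement, single measurement, appropriate when the raters are a sample
  from a larger pool and every rater scores every item.
* **One-way ANOVA** — a check for systematic level differences between
  raters (one group per rater).

Interpretation bands follow the conventional Landis-Koch ladder for kappa
and the Koo-Li ladder for ICC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    DomainError,
    InsufficientDataError,
    ShapeError,
)

__all__ = [
    "RatingsMatrix",
    "KappaResult",
    "IccResult",
    "AnovaResult",
    "cohen_kappa",
    "icc_pairwise",
    "icc_pooled",
    "systematic_difference",
    "agreement_table",
    "interpret_kappa",
    "interpret_icc",
]

_ICC_MODELS = {"ICC1": "ICC1", "ICC2": "ICC2", "ICC3": "ICC3"}


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch style agreement band for a kappa value."""
    if kappa <= 0.0:
        return "none"
    if kappa <= 0.20:
        return "none to slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def interpret_icc(icc: float) -> str:
    """Koo-Li reliability band for an ICC value."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class RatingsMatrix:
    """Scores assigned by ``m`` raters to ``n`` items (no missing cells)."""

    scores: np.ndarray
    items: tuple[str, ...] | None = None
    raters: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores)
        if arr.ndim != 2:
            raise ShapeError(f"scores must be 2-D (items x raters), got {arr.shape}")
        n, m = arr.shape
        if n < 2:
            raise InsufficientDataError(f"need >= 2 items, got {n}")
        if m < 2:
            raise InsufficientDataError(f"need >= 2 raters, got {m}")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ShapeError("ratings matrix contains missing/non-finite cells")
        object.__setattr__(self, "scores", arr)
        items = self.items or tuple(f"item{i+1}" for i in range(n))
        raters = self.raters or tuple(f"rater{j+1}" for j in range(m))
        if len(items) != n or len(raters) != m:
            raise ShapeError("items/raters labels do not match matrix shape")
        object.__setattr__(self, "items", tuple(map(str, items)))
        object.__setattr__(self, "raters", tuple(map(str, raters)))

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    def column(self, rater: int | str) -> np.ndarray:
        if isinstance(rater, str):
            rater = self.raters.index(rater)
        return self.scores[:, rater]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.items),
                            columns=list(self.raters))


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa between two raters.

    ``constant`` is set (and ``kappa``/``se`` are None) when both raters
    assigned one identical score throughout, leaving chance agreement
    undefined; ``observed_agreement`` is still reported (1.0 in that case).
    """

    kappa: float | None
    se: float | None
    observed_agreement: float
    constant: bool
    interpretation: str


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its 95% confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    model: str
    interpretation: str


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA F test for systematic rater differences."""

    f: float
    p: float
    df_between: int
    df_within: int


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ShapeError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


def cohen_kappa(a, b) -> KappaResult:
    """Unweighted Cohen's kappa between two raters' categorical scores.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the marginal products; the standard error is the
    large-sample estimate.  Both-constant-and-identical vectors return the
    ``constant`` flag instead of a number.
    """
    from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.shape != b.shape:
        raise ShapeError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    n = a.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need >= 2 rated items, got {n}")

    observed = float(np.mean(a == b))
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1 and a[0] == b[0]:
        return KappaResult(
            kappa=None,
            se=None,
            observed_agreement=1.0,
            constant=True,
            interpretation="constant (100% agreement)",
        )

    cats = np.union1d(a, b)
    table = (
        pd.crosstab(pd.Categorical(a, categories=cats),
                    pd.Categorical(b, categories=cats), dropna=False)
        .to_numpy()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = _sm_kappa(table, return_results=True)
    kappa = float(res.kappa)
    se = float(np.sqrt(max(float(res.var_kappa), 0.0)))
    return KappaResult(
        kappa=kappa,
        se=se,
        observed_agreement=observed,
        constant=False,
        interpretation=interpret_kappa(kappa),
    )


def _icc_from_frame(scores: np.ndarray, model: str) -> IccResult:
    import pingouin as pg

    model = model.upper()
    if model not in _ICC_MODELS:
        raise DomainError(f"unknown ICC model {model!r}; choose from {sorted(_ICC_MODELS)}")
    n, m = scores.shape
    if n < 3:
        raise InsufficientDataError(f"ICC needs >= 3 items, got {n}")
    if np.ptp(scores.mean(axis=1)) == 0:
        raise DegenerateVarianceError(
            "zero between-item variance: every item has the same mean score, "
            "so no reliability can be apportioned"
        )
    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n), m),
            "rater": np.tile(np.arange(m), n),
            "score": scores.astype(float).ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(
            long, targets="item", raters="rater", ratings="score"
        )
    # pingouin rows: ICC1=one-way random, ICC2="ICC(A,1)" absolute agreement,
    # ICC3="ICC(C,1)" consistency; all single-measurement.
    row_name = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}[model]
    row = table.set_index("Type").loc[row_name]
    icc = float(row["ICC"])
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    if math.isclose(icc, 1.0, abs_tol=1e-12) and not math.isfinite(ci_low):
        # MSE = 0 (raters numerically identical): the F-based CI degenerates.
        ci_low = ci_high = 1.0
    return IccResult(
        icc=icc,
        ci_low=ci_low,
        ci_high=ci_high,
        model=model,
        interpretation=interpret_icc(icc),
    )


def icc_pairwise(a, b, model: str = "ICC2") -> IccResult:
    """ICC between two raters' score vectors.

    Default model ICC(2,1): two-way random effects, absolute agreement,
    single measurement, with the F-distribution 95% confidence interval.
    """
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.shape != b.shape:
        raise ShapeError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return _icc_from_frame(np.column_stack([a, b]).astype(float), model)


def icc_pooled(ratings: RatingsMatrix, model: str = "ICC2") -> IccResult:
    """Single ICC over all raters of a ratings matrix."""
    return _icc_from_frame(ratings.scores.astype(float), model)


def systematic_difference(groups) -> AnovaResult:
    """One-way ANOVA over observer groups (one group per rater).

    F = MS_between / MS_within; a small F (large p) means no systematic
    level difference between raters.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups for one-way ANOVA")
    for g in groups:
        if g.ndim != 1:
            raise ShapeError("each group must be a 1-D score vector")
        if g.shape[0] < 2:
            raise InsufficientDataError("each group needs >= 2 scores")
    f, p = stats.f_oneway(*groups)
    n_total = sum(g.shape[0] for g in groups)
    return AnovaResult(
        f=float(f),
        p=float(p),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
    )


def agreement_table(ratings: RatingsMatrix, icc_model: str = "ICC2") -> pd.DataFrame:
    """Tidy per-pair agreement report plus the pooled ANOVA row.

    One kappa row and one ICC row per rater pair, then a single one-way
    ANOVA row across all raters.  Columns: pair, statistic, estimate, se,
    ci_low, ci_high, p, interpretation.
    """
    rows = []
    m = ratings.n_raters
    for i in range(m):
        for j in range(i + 1, m):
            pair = f"{ratings.raters[i]} vs {ratings.raters[j]}"
            a, b = ratings.column(i), ratings.column(j)
            k = cohen_kappa(a, b)
            rows.append(
                {
                    "pair": pair,
                    "statistic": "kappa",
                    "estimate": k.kappa,
                    "se": k.se,
                    "ci_low": None,
                    "ci_high": None,
                    "p": None,
                    "interpretation": k.interpretation,
                }
            )
            try:
                icc = icc_pairwise(a, b, model=icc_model)
                rows.append(
                    {
                        "pair": pair,
                        "statistic": icc.model,
                        "estimate": icc.icc,
                        "se": None,
                        "ci_low": icc.ci_low,
                        "ci_high": icc.ci_high,
                        "p": None,
                        "interpretation": icc.interpretation,
                    }
                )
            except DegenerateVarianceError:
                rows.append(
                    {
                        "pair": pair,
                        "statistic": icc_model,
                        "estimate": None,
                        "se": None,
                        "ci_low": None,
                        "ci_high": None,
                        "p": None,
                        "interpretation": "degenerate (no between-item variance)",
                    }
                )
    anova = systematic_difference([ratings.column(j) for j in range(m)])
    rows.append(
        {
            "pair": "all raters",
            "statistic": "anova_F",
            "estimate": anova.f,
            "se": None,
            "ci_low": None,
            "ci_high": None,
            "p": anova.p,
            "interpretation": (
                f"F({anova.df_between}, {anova.df_within})"
            ),
        }
    )
    return pd.DataFrame(rows)
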