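"""Between-group statistics on population-mean sensilla traits.

Each population contributes a single value per trait (its mean over
females), avoiding pseudoreplication from uneven sampling.  The battery
compares: the two species (Welch's unequal-variance t), the three patry
classes within E. carunculatum (Kruskal–Wallis), the two sampled patry
classes within E. anna (Welch), and sympatric-vs-allopatric variances
(Bartlett).  Coverage proportions are arcsine-square-root transformed
before parametric tests.  All p-values are two-sided and no correction is
applied across the trait battery (FDR is used only for the pairwise KDE
table in :mod:`platemorph.spatial`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "welch_t_test",
    "kruskal_wallis",
    "bartlett_test",
    "linear_regression",
    "arcsine_sqrt",
    "run_comparison_battery",
]

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """Outcome of one statistical contrast."""

    test: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    trait: str | None = None
    transform: str | None = None
    group_labels: tuple = ()
    group_sizes: tuple = ()
    group_means: tuple = ()
    group_sems: tuple = ()
    extra: dict = field(default_factory=dict)


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def welch_t_test(a, b, labels: tuple = ("a", "b")) -> ComparisonResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degrees of freedom follow Welch–Satterthwaite and are generally
    fractional.
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t-test needs >=2 values per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return ComparisonResult(
                "welch_t", 0.0, 1.0, df=float(len(a) + len(b) - 2),
                group_labels=labels, group_sizes=(len(a), len(b)),
                group_means=(float(np.mean(a)), float(np.mean(b))),
                group_sems=(0.0, 0.0),
            )
        raise ValueError("both group variances are zero")
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        test="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        group_labels=labels,
        group_sizes=(len(a), len(b)),
        group_means=(float(np.mean(a)), float(np.mean(b))),
        group_sems=(float(sps.sem(a)), float(sps.sem(b))),
    )


def kruskal_wallis(groups, labels: tuple = ()) -> ComparisonResult:
    """Kruskal–Wallis rank test with tie correction; chi-square reference.

    Empty groups are dropped (with a log entry) and k reduced accordingly.
    """
    cleaned, kept = [], []
    for i, g in enumerate(groups):
        arr = _clean(g)
        if len(arr) == 0:
            logger.warning("kruskal_wallis: dropping empty group %d", i)
            continue
        cleaned.append(arr)
        kept.append(labels[i] if labels else str(i))
    if len(cleaned) < 2:
        raise ValueError("Kruskal–Wallis needs >=2 non-empty groups")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical; H undefined")
    stat, p = sps.kruskal(*cleaned)
    return ComparisonResult(
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        df=float(len(cleaned) - 1),
        group_labels=tuple(kept),
        group_sizes=tuple(len(g) for g in cleaned),
        group_means=tuple(float(np.mean(g)) for g in cleaned),
        group_sems=tuple(float(sps.sem(g)) if len(g) > 1 else np.nan for g in cleaned),
    )


def bartlett_test(groups, labels: tuple = ()) -> ComparisonResult:
    """Bartlett's test of equal variances; chi-square with k-1 df."""
    cleaned = [_clean(g) for g in groups]
    if any(len(g) < 2 for g in cleaned) or len(cleaned) < 2:
        raise ValueError("Bartlett test needs >=2 groups of >=2 values")
    if any(np.var(g, ddof=1) == 0.0 for g in cleaned):
        raise ValueError("Bartlett test undefined for a zero-variance group")
    stat, p = sps.bartlett(*cleaned)
    return ComparisonResult(
        test="bartlett",
        statistic=float(stat),
        p_value=float(p),
        df=float(len(cleaned) - 1),
        group_labels=tuple(labels) if labels else tuple(str(i) for i in range(len(cleaned))),
        group_sizes=tuple(len(g) for g in cleaned),
        group_means=tuple(float(np.mean(g)) for g in cleaned),
        group_sems=tuple(float(sps.sem(g)) for g in cleaned),
    )


def linear_regression(x, y) -> dict:
    """Ordinary least squares y ~ x with adjusted R^2 and the overall F test."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("regression needs >=3 complete observations")
    if np.var(x) == 0.0:
        raise ValueError("constant predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r2_adj": float(model.rsquared_adj),
        "F": float(model.fvalue),
        "df": (int(model.df_model), int(model.df_resid)),
        "p_value": float(model.f_pvalue),
        "n": int(len(x)),
    }


def arcsine_sqrt(p):
    """Variance-stabilizing transform for proportions: asin(sqrt(p)), radians."""
    arr = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((arr[np.isfinite(arr)] < 0) | (arr[np.isfinite(arr)] > 1)):
            raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


#: traits entering the battery, and whether they are proportions
_BATTERY_TRAITS = (
    ("sensilla_count", False),
    ("coverage_proportion", True),
    ("density", False),
    ("mean_nnd", False),
)


def run_comparison_battery(population_means: pd.DataFrame) -> pd.DataFrame:
    """The full trait battery on a population-mean table.

    Expects the output of :func:`platemorph.traits.aggregate_populations`
    (columns species, population_id, patry, and the trait columns).  Per
    trait it runs: species contrast (Welch), E. carunculatum three-class
    patry contrast (Kruskal–Wallis), E. anna sympatric-vs-locally-allopatric
    contrast (Welch), and a sympatric-vs-allopatric Bartlett variance
    contrast within E. carunculatum.  Contrasts whose classes are missing or
    too small are skipped with a log entry.
    """
    df = population_means
    rows = []

    def _record(res: ComparisonResult | None, contrast: str, trait: str, transform):
        if res is None:
            return
        rows.append(
            {
                "contrast": contrast,
                "trait": trait,
                "test": res.test,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "transform": transform,
                "group_labels": "|".join(map(str, res.group_labels)),
                "group_sizes": "|".join(map(str, res.group_sizes)),
                "group_means": "|".join(f"{m:.6g}" for m in res.group_means),
                "group_sems": "|".join(f"{s:.6g}" for s in res.group_sems),
            }
        )

    for trait, is_prop in _BATTERY_TRAITS:
        if trait not in df.columns:
            continue
        values = df[trait].astype(float)
        transform = None
        if is_prop:
            values = pd.Series(arcsine_sqrt(values.to_numpy()), index=df.index)
            transform = "arcsine_sqrt"

        def _vals(mask) -> np.ndarray:
            return _clean(values[mask])

        # species contrast on population means
        a = _vals(df["species"] == "E_anna")
        b = _vals(df["species"] == "E_carunculatum")
        if len(a) >= 2 and len(b) >= 2:
            _record(
                welch_t_test(a, b, labels=("E_anna", "E_carunculatum")),
                "species", trait, transform,
            )
        else:
            logger.warning("battery: species contrast skipped for %s", trait)

        # E. carunculatum three-class patry contrast
        ec = df["species"] == "E_carunculatum"
        groups, labels = [], []
        for patry in ("sympatric", "locally_allopatric", "allopatric"):
            g = _vals(ec & (df["patry"] == patry))
            if len(g):
                groups.append(g)
                labels.append(patry)
        if len(groups) >= 2:
            _record(kruskal_wallis(groups, tuple(labels)), "Ec_patry", trait, transform)
        else:
            logger.warning("battery: Ec patry contrast skipped for %s", trait)

        # E. anna two-class contrast
        ea = df["species"] == "E_anna"
        sym = _vals(ea & (df["patry"] == "sympatric"))
        lal = _vals(ea & (df["patry"] == "locally_allopatric"))
        if len(sym) >= 2 and len(lal) >= 2:
            _record(
                welch_t_test(lal, sym, labels=("locally_allopatric", "sympatric")),
                "Ea_patry", trait, transform,
            )
        else:
            logger.warning("battery: Ea patry contrast skipped for %s", trait)

        # variance contrast: sympatric vs fully allopatric Ec populations
        vs = _vals(ec & (df["patry"] == "sympatric"))
        va = _vals(ec & (df["patry"] == "allopatric"))
        if len(vs) >= 2 and len(va) >= 2 and np.var(vs, ddof=1) > 0 and np.var(va, ddof=1) > 0:
            _record(
                bartlett_test([vs, va], ("sympatric", "allopatric")),
                "Ec_variance", trait, transform,
            )
        else:
            logger.warning("battery: Ec variance contrast skipped for %s", trait)

    return pd.DataFrame(rows)
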