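"""Study-level statistics: effect size, power, transformations, mixed models.

The group-comparison contract is a linear mixed model with diagnosis,
sex and their interaction as fixed effects and sample nested in case as
random effects, followed by ANOVA-style F tests (containment degrees of
freedom: cases minus case-level parameters) and Tukey-adjusted pairwise
contrasts between the four diagnosis × sex cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .core_io import MeasurementTable
from .exceptions import FormatError

__all__ = [
    "GroupSummary",
    "GroupModelResult",
    "effect_size",
    "power_two_sample",
    "tukey_transform",
    "fit_group_model",
    "receptor_occupancy",
    "spearman_correlation",
    "summarize_group",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise FormatError("sd must be >= 0")
        if self.n is not None and self.n < 1:
            raise FormatError("n must be >= 1")


def summarize_group(label: str, values) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    return GroupSummary(
        label=label,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n=len(values),
    )


def effect_size(
    positive: GroupSummary, control: GroupSummary, *, pooled: bool = False
) -> float:
    """Standardized mean difference between two summarized groups.

    By default the difference is divided by the positive group's own
    dispersion; ``pooled=True`` uses the classical pooled-sd
    denominator instead (requires n for both groups).
    """
    if positive.sd == 0 and control.sd == 0:
        raise FormatError("both group dispersions are zero")
    if pooled:
        if positive.n is None or control.n is None:
            raise FormatError("pooled effect size requires group sizes")
        num = (positive.n - 1) * positive.sd**2 + (control.n - 1) * control.sd**2
        denom = np.sqrt(num / (positive.n + control.n - 2))
    else:
        denom = positive.sd
    if denom == 0:
        raise FormatError("zero denominator dispersion")
    return (positive.mean - control.mean) / denom


def power_two_sample(
    d: float, n1: int, n2: int, alpha: float = 0.05, sides: int = 2
) -> float:
    """Power of the two-sample t-test via the noncentral t distribution.

    Noncentrality is ``d·sqrt(n1·n2/(n1+n2))`` on ``n1+n2−2`` degrees of
    freedom.
    """
    if n1 < 2 or n2 < 2:
        raise FormatError("group sizes must be >= 2")
    if not np.isfinite(d):
        raise FormatError("effect size must be finite")
    if sides not in (1, 2):
        raise FormatError("sides must be 1 or 2")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if sides == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        upper = sps.nct.sf(tcrit, df, ncp)
        lower = sps.nct.cdf(-tcrit, df, ncp)
        # scipy's nct tail probabilities underflow to NaN deep in the
        # wrong-direction tail, where the true contribution is ~0
        if not np.isfinite(lower):
            lower = 0.0
        power = upper + lower
    else:
        tcrit = sps.t.ppf(1 - alpha, df)
        power = sps.nct.sf(tcrit, df, ncp)
    if not np.isfinite(power):
        raise FormatError(f"power underflow at d={d}, n1={n1}, n2={n2}")
    return float(np.clip(power, 0.0, 1.0))


LADDER_EXPONENTS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


def _ladder_apply(values: np.ndarray, exponent: float) -> np.ndarray:
    if exponent == 0.0:
        return np.log(values)
    if exponent < 0:
        return -(values**exponent)  # negated to preserve ordering
    return values**exponent


def tukey_transform(
    values, exponents: tuple = LADDER_EXPONENTS
) -> tuple[np.ndarray, float]:
    """Ladder-of-powers transform maximizing Shapiro–Wilk normality.

    Values are shifted to be strictly positive when an exponent requires
    it.  Returns (transformed values, chosen exponent); exponent 1
    returns the input unchanged.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        warnings.warn("constant or tiny sample: identity transform returned", stacklevel=2)
        return values.copy(), 1.0
    vmin = values.min()
    shifted = values - vmin + 1.0 if vmin <= 0 else values
    best_w, best_p = -np.inf, 1.0
    best: np.ndarray | None = None
    for p in exponents:
        data = values if p == 1.0 else _ladder_apply(shifted, p)
        if not np.all(np.isfinite(data)) or np.ptp(data) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = sps.shapiro(data).statistic
        if w > best_w:
            best_w, best_p, best = w, p, data
    if best is None:  # pragma: no cover - defensive
        return values.copy(), 1.0
    if best_p == 1.0:
        return values.copy(), 1.0
    return best, best_p


def receptor_occupancy(concentration: float, ki: float) -> float:
    """Percent receptor occupancy: 100 · (c/Ki) / ((c/Ki) + 1)."""
    if ki <= 0:
        raise FormatError("Ki must be strictly positive")
    if concentration < 0:
        raise FormatError("concentration must be non-negative")
    ratio = concentration / ki
    return 100.0 * ratio / (ratio + 1.0)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Thin convenience over scipy's Spearman rank correlation."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------


@dataclass
class GroupModelResult:
    formula: str
    fixed_effects: pd.DataFrame  # term, F, df1, df2, p
    contrasts: pd.DataFrame  # cell pair, estimate, se, q, p_tukey
    cell_means: pd.DataFrame
    n_cases: int
    note: str = ""
    mixedlm_result: object = field(default=None, repr=False)

    def term_p(self, term: str) -> float:
        row = self.fixed_effects[self.fixed_effects.term == term]
        if row.empty:
            raise KeyError(f"no fixed-effect term {term!r}")
        return float(row.p.iloc[0])


def _cell_row(exog_names: list[str], levels: dict[str, str]) -> np.ndarray:
    """Design row for a factor-level cell under treatment coding."""

    def piece(name: str) -> float:
        if name == "Intercept":
            return 1.0
        val = 1.0
        for part in name.split(":"):
            # e.g. "C(diagnosis)[T.control]"
            factor = part[part.index("(") + 1 : part.index(")")]
            level = part[part.index("[T.") + 3 : -1]
            if levels.get(factor) != level:
                return 0.0
        return val

    return np.array([piece(n) for n in exog_names])


def fit_group_model(table: MeasurementTable, measurement: str) -> GroupModelResult:
    """Fit diagnosis*sex with sample nested in case as random effects.

    Numerics are delegated to statsmodels' MixedLM; the contract here is
    the model formula, containment-df F tests and Tukey-adjusted cell
    contrasts.  With a single sex present the model downgrades to
    diagnosis only and says so in ``note``.
    """
    df = table.frame[table.frame.measurement == measurement].copy()
    if df.empty:
        raise FormatError(f"no rows for measurement {measurement!r}")
    df["value"] = df["value"].astype(float)
    per_dx = df.groupby("diagnosis")["case_id"].nunique()
    if len(per_dx) < 2 or (per_dx < 2).any():
        raise FormatError("need >= 2 cases per diagnosis group")

    note = ""
    sexes = sorted(df["sex"].unique())
    if len(sexes) < 2:
        formula = "value ~ C(diagnosis)"
        note = "single sex present: model downgraded to diagnosis-only fixed effect"
    else:
        formula = "value ~ C(diagnosis) * C(sex)"

    df["sample_key"] = df["case_id"].astype(str) + ":" + df["sample_id"].astype(str)
    replicated = df.groupby("sample_key").size().max() > 1
    vc = {"sample": "0 + C(sample_key)"} if replicated else None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            formula, groups="case_id", re_formula="1", vc_formula=vc, data=df
        )
        result = None
        for method in ("bfgs", "lbfgs", "cg", "powell"):
            try:
                result = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if result is None:
            raise FormatError("mixed model failed to converge with any optimizer")

    fe = result.fe_params
    cov = result.cov_params().loc[fe.index, fe.index].to_numpy()
    exog_names = list(fe.index)
    n_cases = df["case_id"].nunique()
    df2 = max(n_cases - len(exog_names), 1)

    terms: dict[str, list[int]] = {}
    for j, name in enumerate(exog_names):
        if name == "Intercept":
            continue
        if ":" in name:
            term = "diagnosis:sex"
        elif "diagnosis" in name:
            term = "diagnosis"
        else:
            term = "sex"
        terms.setdefault(term, []).append(j)

    rows = []
    b = fe.to_numpy()
    for term, idx in terms.items():
        L = np.zeros((len(idx), len(b)))
        for k, j in enumerate(idx):
            L[k, j] = 1.0
        est = L @ b
        vmat = L @ cov @ L.T
        fstat = float(est @ np.linalg.solve(vmat, est)) / len(idx)
        p = float(sps.f.sf(fstat, len(idx), df2))
        rows.append({"term": term, "F": fstat, "df1": len(idx), "df2": df2, "p": p})
    fixed_effects = pd.DataFrame(rows)

    # cell means and Tukey-adjusted pairwise contrasts
    dx_levels = sorted(df["diagnosis"].unique())
    cells = list(itertools.product(dx_levels, sexes)) if len(sexes) > 1 else [
        (d, "") for d in dx_levels
    ]
    cell_rows = []
    design_rows = {}
    for d, s in cells:
        levels = {"diagnosis": d, "sex": s}
        x = _cell_row(exog_names, levels)
        design_rows[(d, s)] = x
        cell_rows.append(
            {
                "diagnosis": d,
                "sex": s,
                "mean": float(x @ b),
                "se": float(np.sqrt(x @ cov @ x)),
            }
        )
    cell_means = pd.DataFrame(cell_rows)

    k = len(cells)
    contrast_rows = []
    for (c1, c2) in itertools.combinations(cells, 2):
        diff = design_rows[c1] - design_rows[c2]
        est = float(diff @ b)
        se = float(np.sqrt(diff @ cov @ diff))
        if se == 0:
            continue
        q = abs(est) / se * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df2)) if k > 1 else np.nan
        contrast_rows.append(
            {
                "cell_1": "/".join(filter(None, c1)),
                "cell_2": "/".join(filter(None, c2)),
                "estimate": est,
                "se": se,
                "q": q,
                "p_tukey": p,
            }
        )
    contrasts = pd.DataFrame(contrast_rows)

    return GroupModelResult(
        formula=formula + " + (1|case/sample)",
        fixed_effects=fixed_effects,
        contrasts=contrasts,
        cell_means=cell_means,
        n_cases=n_cases,
        note=note,
        mixedlm_result=result,
    )
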