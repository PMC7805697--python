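"""Mixed-model analysis stage: type II Wald tables, pruning, Levene's test.

Each response is modelled with a linear mixed model (REML) carrying a
per-subject random intercept and the full factorial of the fixed factors:
condition (unordered), correct-door location (unordered), and either the
ordered test factor (levels 0/10/20, polynomial contrasts) or the numeric
trial covariate.  Unordered factors use sum-to-zero contrasts so that
marginality-respecting type II tests are meaningful.

For every term a reduced model containing the term plus all terms of
equal or lower order (i.e. excluding its strict higher-order relatives)
is fitted, and the term's coefficient block is tested with a Wald
chi-square against that fit.  A second table is produced after discarding
interaction terms that were not significant (p >= 0.05) on the full-model
table, respecting marginality; both tables are always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "AnovaRow",
    "AnovaTable",
    "LmmResult",
    "fit_lmm_type2",
    "corrected_alpha",
    "levene_variability",
    "LeveneResult",
    "summarize_study",
    "prepare_analysis_frame",
]

#: patsy factor tokens keyed by the human-readable factor name
_TOKENS = {
    "Condition": "C(Condition, Sum)",
    "CorrectDoorLocation": "C(CorrectDoorLocation, Sum)",
    "Test": "C(Test, Poly)",
    "Trial": "Trial",
}

_PRUNE_ALPHA = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """A response plus its ordered fixed factors (random: subject intercept).

    Exactly one of ``Test`` / ``Trial`` may appear among the factors.
    """

    response: str
    factors: Tuple[str, ...] = ("Condition", "CorrectDoorLocation", "Test")
    max_order: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.factors) - set(_TOKENS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        if ("Test" in self.factors) == ("Trial" in self.factors):
            raise ValueError("exactly one of Test/Trial must be a factor")

    def terms(self) -> List[Tuple[str, ...]]:
        """All factor subsets up to ``max_order``, by order then position."""
        from itertools import combinations

        out: List[Tuple[str, ...]] = []
        for k in range(1, min(self.max_order, len(self.factors)) + 1):
            out.extend(combinations(self.factors, k))
        return out


@dataclass(frozen=True)
class AnovaRow:
    term: str
    chisq: float
    df: int
    p: float


@dataclass
class AnovaTable:
    rows: List[AnovaRow]
    warnings: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.term, r.chisq, r.df, r.p) for r in self.rows],
            columns=["term", "chisq", "df", "p"])

    def p_for(self, term: str) -> float:
        for r in self.rows:
            if r.term == term:
                return r.p
        raise KeyError(term)

    def to_dict(self) -> dict:
        return {
            "rows": [{"term": r.term, "chisq": r.chisq, "df": r.df, "p": r.p}
                     for r in self.rows],
            "warnings": list(self.warnings),
        }

    def __str__(self) -> str:
        lines = [f"{'term':<42}{'chisq':>10}{'df':>4}{'p':>10}"]
        for r in self.rows:
            lines.append(f"{r.term:<42}{r.chisq:>10.2f}{r.df:>4}{r.p:>10.3g}")
        return "\n".join(lines)


@dataclass
class LmmResult:
    full: AnovaTable
    pruned: AnovaTable
    retained_terms: List[str]
    fixed_effects: Dict[str, float]


def _term_label(term: Tuple[str, ...]) -> str:
    return ":".join(term)


def _formula(response: str, terms: Iterable[Tuple[str, ...]]) -> str:
    rhs = " + ".join(":".join(_TOKENS[f] for f in t) for t in terms)
    return f"{response} ~ {rhs}" if rhs else f"{response} ~ 1"


def _check_cells(data: pd.DataFrame, spec: ModelSpec) -> None:
    cat = [f for f in spec.factors if f != "Trial"]
    if not cat:
        return
    counts = data.groupby(cat, observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        raise ValueError(f"empty design cell {dict(zip(cat, np.atleast_1d(cell)))}")
    groups = data.groupby(cat, observed=False)["subject"].nunique()
    if (groups < 2).any():
        bad = groups[groups < 2].index[0]
        raise ValueError(
            f"design cell {dict(zip(cat, np.atleast_1d(bad)))} has < 2 subjects")


def _fit_mixedlm(formula: str, data: pd.DataFrame, caught: List[str]):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data, groups=data["subject"])
        res = None
        last_exc: Optional[Exception] = None
        # the random-intercept variance can hit the boundary; fall back to
        # derivative-free optimizers when gradient steps go singular
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=True, method=method, maxiter=2000)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if res is None:
            raise RuntimeError(
                f"mixed model failed to fit: {formula}") from last_exc
    for w in wrec:
        msg = str(w.message)
        if "converge" in msg.lower() or "singular" in msg.lower() \
                or "boundary" in msg.lower():
            caught.append(msg)
    return res


def _wald_block(res, term_tokens: str) -> AnovaRow:
    di = res.model.data.design_info
    sl = di.term_name_slices[term_tokens]
    k_fe = len(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    b = np.asarray(res.fe_params)[sl]
    v = cov[sl, sl]
    chisq = float(b @ np.linalg.solve(v, b))
    df = len(b)
    return AnovaRow("", chisq, df, float(sps.chi2.sf(chisq, df)))


def _type2_table(data: pd.DataFrame, spec: ModelSpec,
                 term_set: List[Tuple[str, ...]],
                 wald_terms: Optional[Sequence[Tuple[str, ...]]] = None
                 ) -> AnovaTable:
    caught: List[str] = []
    rows: List[AnovaRow] = []
    cache: Dict[frozenset, object] = {}
    test_list = list(wald_terms) if wald_terms is not None else term_set
    for term in test_list:
        included = [t for t in term_set
                    if not (set(t) > set(term))]  # drop strict supersets
        key = frozenset(map(tuple, included))
        if key not in cache:
            cache[key] = _fit_mixedlm(_formula(spec.response, included),
                                      data, caught)
        res = cache[key]
        tokens = ":".join(_TOKENS[f] for f in term)
        row = _wald_block(res, tokens)
        rows.append(AnovaRow(_term_label(term), row.chisq, row.df, row.p))
    return AnovaTable(rows, warnings=sorted(set(caught)))


def fit_lmm_type2(data: pd.DataFrame, spec: ModelSpec,
                  wald_terms: Optional[Sequence[Tuple[str, ...]]] = None
                  ) -> LmmResult:
    """Fit the full factorial mixed model and produce type II Wald tables.

    Returns both the full-model table and the table after discarding
    non-significant interactions.  ``wald_terms`` restricts which terms
    are tested (all, by default) — useful in simulation studies.
    """
    needed = ["subject", spec.response] + [f for f in spec.factors]
    data = data.dropna(subset=[spec.response]).copy()
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if data[spec.response].nunique() <= 1:
        raise ValueError(f"response {spec.response!r} is degenerate")
    _check_cells(data, spec)

    all_terms = spec.terms()
    full = _type2_table(data, spec, all_terms, wald_terms)

    # prune non-significant interactions, respecting marginality
    if wald_terms is None:
        pvals = {r.term: r.p for r in full.rows}
        retained = [t for t in all_terms if len(t) == 1]
        for order in range(max(len(t) for t in all_terms), 1, -1):
            for t in (t for t in all_terms if len(t) == order):
                label = _term_label(t)
                kept_above = any(set(t) < set(r) for r in retained)
                if kept_above or pvals[label] < _PRUNE_ALPHA:
                    retained.append(t)
        retained = sorted(retained, key=lambda t: (len(t), all_terms.index(t)))
        pruned = _type2_table(data, spec, retained)
    else:
        retained = all_terms
        pruned = full

    caught: List[str] = []
    res = _fit_mixedlm(_formula(spec.response, retained), data, caught)
    fe = {name: float(v) for name, v in res.fe_params.items()}
    return LmmResult(full=full, pruned=pruned,
                     retained_terms=[_term_label(t) for t in retained],
                     fixed_effects=fe)


def corrected_alpha(nominal: float, n_tests: int) -> float:
    """Bonferroni-corrected significance threshold: ``nominal / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < nominal <= 1:
        raise ValueError("nominal alpha must lie in (0, 1]")
    return nominal / n_tests


@dataclass(frozen=True)
class LeveneResult:
    F: float
    df1: int
    df2: int
    p: float

    def to_dict(self) -> dict:
        return {"F": self.F, "df1": self.df1, "df2": self.df2, "p": self.p}


def levene_variability(data: pd.DataFrame, response: str,
                       grouping: Sequence[str]) -> LeveneResult:
    """Brown-Forsythe test of variance homogeneity across design groups.

    Absolute deviations from group medians are compared with a one-way
    ANOVA, reporting F with (k - 1, N - k) degrees of freedom.
    """
    sub = data.dropna(subset=[response])
    groups = []
    for key, g in sub.groupby(list(grouping), observed=False):
        if len(g) < 2:
            raise ValueError(
                f"group {dict(zip(grouping, np.atleast_1d(key)))} has "
                f"{len(g)} observation(s); need >= 2")
        groups.append(g[response].to_numpy())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    n = sum(len(g) for g in groups)
    # identical deviation profiles across groups: no variability difference
    devs = [np.abs(g - np.median(g)) for g in groups]
    means = np.array([d.mean() for d in devs])
    if np.allclose(means, means[0]):
        return LeveneResult(0.0, k - 1, n - k, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        F, p = sps.levene(*groups, center="median")
    return LeveneResult(float(F), k - 1, n - k, float(p))


def prepare_analysis_frame(metrics: pd.DataFrame, *, test_data: bool
                           ) -> pd.DataFrame:
    """Map a metrics table onto the analysis variable names/codings."""
    df = pd.DataFrame({
        "subject": metrics["subject"],
        "Condition": pd.Categorical(
            metrics["condition"].map({"individual": "Individual",
                                      "social": "Social"})),
        "CorrectDoorLocation": pd.Categorical(
            metrics["door_location"].map({"preferred": "Preferred",
                                          "nonpreferred": "NonPreferred"})),
    })
    if test_data:
        df["Test"] = metrics["session"].astype(int)
    else:
        df["Trial"] = metrics["session"].astype(float)
    for col in ("T", "PI", "theta_C_mean", "RI", "H", "v_mean", "a_mean",
                "omega_mean", "F", "PI_m"):
        if col in metrics.columns:
            df[col] = pd.to_numeric(metrics[col], errors="coerce")
    return df


def summarize_study(training_metrics: pd.DataFrame,
                    test_metrics: pd.DataFrame,
                    *,
                    test_responses: Sequence[str] = ("PI", "theta_C_mean"),
                    training_responses: Sequence[str] = ("T", "PI",
                                                         "theta_C_mean"),
                    nominal_alpha: float = 0.05,
                    conservative: bool = True) -> dict:
    """Run the full analysis stage and emit a machine-readable report.

    Mixed models are fitted for the configured responses on test data
    (ordered Test factor) and training data (numeric Trial), significance
    is flagged at the multiplicity-corrected alpha (conservatively the
    training-data correction, 0.050/3, for both datasets), and variance
    homogeneity of PI is checked across the 12 design groups.
    """
    alpha_test = corrected_alpha(nominal_alpha, len(test_responses))
    alpha_train = corrected_alpha(nominal_alpha, len(training_responses))
    alpha_flag = min(alpha_test, alpha_train) if conservative else None

    report: dict = {
        "alpha": {
            "nominal": nominal_alpha,
            "test_data": alpha_test,
            "training_data": alpha_train,
            "conservative": conservative,
        },
        "test_data": {},
        "training_data": {},
    }

    def run(metrics: pd.DataFrame, responses: Sequence[str], *,
            test_data: bool, alpha: float) -> dict:
        frame = prepare_analysis_frame(metrics, test_data=test_data)
        factors = (("Condition", "CorrectDoorLocation", "Test") if test_data
                   else ("Condition", "Trial", "CorrectDoorLocation"))
        out = {}
        flag_at = alpha_flag if conservative else alpha
        for resp in responses:
            spec = ModelSpec(response=resp, factors=factors)
            fit = fit_lmm_type2(frame, spec)
            out[resp] = {
                "full": fit.full.to_dict(),
                "pruned": fit.pruned.to_dict(),
                "retained_terms": fit.retained_terms,
                "significant_terms": [
                    r.term for r in fit.full.rows if r.p < flag_at],
                "alpha_applied": flag_at,
            }
        return out

    report["test_data"] = run(test_metrics, test_responses,
                              test_data=True, alpha=alpha_test)
    report["training_data"] = run(training_metrics, training_responses,
                                  test_data=False, alpha=alpha_train)

    frame = prepare_analysis_frame(test_metrics, test_data=True)
    report["levene_PI_test_data"] = levene_variability(
        frame, "PI", ["Condition", "CorrectDoorLocation", "Test"]).to_dict()
    return report
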