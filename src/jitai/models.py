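"""Logistic outcome models and their inferential outputs.

The analysis layer follows the model/results idiom: an
:class:`OutcomeLogit` is built from an analysis table and a
:class:`ModelSpec`; ``fit()`` returns an :class:`OutcomeLogitResults`
carrying coefficients, odds ratios with Wald 95% CIs, per-term p-values
with Benjamini-Hochberg flags, the likelihood-ratio test against the
intercept-only model, Tjur's coefficient of discrimination, variance
inflation factors, type-II analysis-of-deviance tests, and
Tukey-style family-wise-adjusted pairwise contrasts for factors with
three or more levels.

Maximum-likelihood fitting is delegated to statsmodels
(binomial GLM via a patsy formula with explicit treatment references);
the derived diagnostics are computed here.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrices
from scipy import stats
from statsmodels.stats.multitest import multipletests


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfectly separated outcome)."""


class RankDeficiencyError(ValueError):
    """The design matrix has exactly collinear (aliased) columns."""


#: Treatment (reference) coding for the categorical predictors, matching
#: the published tables.
REFERENCE_LEVELS = {
    "age_group": "18-35",
    "gender": "man",
    "trigger_source": "system",
    "category": "distract",
    "modality": "conversation",
    "location": "at_desk",
}

_DERIVED_OUTCOMES = {
    "distract_chosen": ("category", "distract"),
    "calm_chosen": ("category", "calm"),
    "address_chosen": ("category", "address"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one logistic outcome model."""

    name: str
    outcome: str
    predictors: tuple[str, ...]
    scope: str  # "per_nudge" | "chosen" | "completed"

    def term(self, predictor: str) -> str:
        if predictor in REFERENCE_LEVELS:
            return f"C({predictor}, Treatment('{REFERENCE_LEVELS[predictor]}'))"
        return predictor

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.term(p) for p in self.predictors)
        return f"__outcome__ ~ {rhs}"


def _pretty_term(raw: str) -> str:
    """patsy design-column name -> compact label, e.g.
    "C(gender, Treatment('man'))[T.woman]" -> "gender[woman]"."""
    if raw == "Intercept":
        return "Intercept"
    if raw.startswith("C("):
        var = raw[2 : raw.index(",")]
        level = raw[raw.index("[T.") + 3 : -1]
        return f"{var}[{level}]"
    return raw


class OutcomeLogit:
    """Maximum-likelihood logistic regression for one binary engagement
    outcome, specified by a :class:`ModelSpec` over an analysis table."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        df = data.copy()
        if spec.outcome in _DERIVED_OUTCOMES:
            col, level = _DERIVED_OUTCOMES[spec.outcome]
            df["__outcome__"] = (df[col] == level).astype(int)
            needed = [col, *spec.predictors]
        else:
            df["__outcome__"] = df[spec.outcome].astype(float).astype(int)
            needed = [spec.outcome, *spec.predictors]
        missing_cols = [c for c in needed if c not in df.columns]
        if missing_cols:
            raise KeyError(f"columns absent from the {spec.scope} table: {missing_cols}")
        if df[needed].isna().any().any():
            bad = [c for c in needed if df[c].isna().any()]
            raise ValueError(f"missing values in scoped columns: {bad}")
        y = df["__outcome__"].astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"outcome {spec.outcome!r} is not binary")
        self.data = df

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "OutcomeLogit":
        return cls(data, spec)

    def _design(self) -> tuple[np.ndarray, np.ndarray, object]:
        y, X = dmatrices(self.spec.formula, self.data, return_type="dataframe")
        return np.asarray(y).ravel(), X, X.design_info

    def fit(self) -> "OutcomeLogitResults":
        y, X, design_info = self._design()
        Xm = np.asarray(X)
        rank = np.linalg.matrix_rank(Xm)
        if rank < Xm.shape[1]:
            aliased = _aliased_columns(Xm, list(X.columns))
            raise RankDeficiencyError(f"aliased design columns: {aliased}")
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        res = glm.fit()
        if not res.converged:
            raise SeparationError("IRLS did not converge")
        if np.max(np.abs(res.params.values[1:] if len(res.params) > 1 else res.params.values)) > 15 or np.any(res.bse > 80):
            raise SeparationError(
                "diverging coefficients / standard errors indicate (quasi-)separation"
            )
        return OutcomeLogitResults(self, res, X, y, design_info)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            aliased.append(names[j])
    return aliased


class OutcomeLogitResults:
    """Fitted logistic outcome model with the derived inferential outputs."""

    def __init__(self, model: OutcomeLogit, glm_results, X: pd.DataFrame,
                 y: np.ndarray, design_info):
        self.model = model
        self.spec = model.spec
        self._res = glm_results
        self._X = X
        self._y = y
        self._design_info = design_info
        self.nobs = int(glm_results.nobs)
        self.converged = bool(glm_results.converged)

    # -- coefficient-level outputs ------------------------------------
    @property
    def term_names(self) -> list[str]:
        return [_pretty_term(c) for c in self._X.columns]

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params.values, index=self.term_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.bse.values, index=self.term_names)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald CI for the odds ratios (symmetric on the log-odds scale)."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"or_lower": lo, "or_upper": hi})

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self._res.pvalues.values, index=self.term_names)

    def bh_flags(self, alpha: float = 0.05) -> pd.Series:
        """Benjamini-Hochberg significance flags over the model's
        non-intercept predictor p-values."""
        mask = [t != "Intercept" for t in self.term_names]
        flags = pd.Series(False, index=self.term_names)
        ps = self.pvalues[mask]
        if len(ps):
            flags[mask] = bh_adjust(ps.values, alpha)
        return flags

    # -- model-level outputs ------------------------------------------
    def lr_test_vs_null(self) -> tuple[float, int, float]:
        """Analysis of deviance against the intercept-only model fitted on
        the identical rows: (chi2, df, p)."""
        chi2 = float(self._res.null_deviance - self._res.deviance)
        df = int(self._res.df_model)
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        return chi2, df, p

    def tjur_r2(self) -> float:
        """Tjur's coefficient of discrimination: mean fitted probability
        among events minus mean among non-events."""
        mu = np.asarray(self._res.fittedvalues)
        events = self._y == 1
        if events.all() or (~events).all():
            raise ValueError("Tjur R^2 undefined for a one-class outcome")
        return float(mu[events].mean() - mu[~events].mean())

    def vif(self) -> pd.Series:
        """Variance inflation factor per non-intercept design column."""
        cols = [c for c in self._X.columns if c != "Intercept"]
        return vif(self._X[cols], names=[_pretty_term(c) for c in cols])

    def type2_anova(self) -> pd.DataFrame:
        """Per-term type-II analysis of deviance: for every predictor,
        the LR test of the model without that term (all of its columns)
        against the full model."""
        rows = []
        full_dev = self._res.deviance
        for pred in self.spec.predictors:
            term = self.spec.term(pred)
            slice_ = self._design_info.slice(term)
            keep = [
                c for i, c in enumerate(self._X.columns)
                if not (slice_.start <= i < slice_.stop)
            ]
            df_term = slice_.stop - slice_.start
            try:
                reduced = sm.GLM(
                    self._y, self._X[keep], family=sm.families.Binomial()
                ).fit()
                chi2 = float(reduced.deviance - full_dev)
                p = float(stats.chi2.sf(chi2, df_term))
                rows.append({"term": pred, "chi2": chi2, "df": df_term, "p": p})
            except Exception as exc:  # noqa: BLE001 - per-term failures reported
                rows.append({"term": pred, "chi2": np.nan, "df": df_term,
                             "p": np.nan, "error": str(exc)})
        return pd.DataFrame(rows).set_index("term")

    def tukey_pairwise(
        self, factor: str, nsim: int = 200_000, seed: int = 0
    ) -> pd.DataFrame:
        """All pairwise level contrasts of a >= 3-level factor on the
        log-odds scale, with single-step family-wise-adjusted p-values.

        The adjustment is the multivariate-normal analogue of Tukey's HSD
        for a generalized linear model: the reference distribution of the
        maximum |z| over the contrast family is evaluated by (seeded)
        Monte-Carlo under the estimated joint normal of the contrasts.
        """
        if factor not in REFERENCE_LEVELS:
            raise ValueError(f"{factor!r} is not a categorical model factor")
        levels = sorted(self.model.data[factor].astype(str).unique())
        if len(levels) < 3:
            raise ValueError(
                f"factor {factor!r} has {len(levels)} levels; use the Wald "
                "test of its single coefficient instead"
            )
        term = self.spec.term(factor)
        slice_ = self._design_info.slice(term)
        cols = list(range(slice_.start, slice_.stop))
        ref = REFERENCE_LEVELS[factor]
        nonref = [
            _pretty_term(self._X.columns[i]).split("[")[1].rstrip("]") for i in cols
        ]
        k = len(self._X.columns)

        def level_vec(level: str) -> np.ndarray:
            v = np.zeros(k)
            if level != ref:
                v[cols[nonref.index(level)]] = 1.0
            return v

        pairs = list(itertools.combinations(levels, 2))
        C = np.array([level_vec(a) - level_vec(b) for a, b in pairs])
        beta = np.asarray(self._res.params)
        cov = np.asarray(self._res.cov_params())
        est = C @ beta
        cse = np.sqrt(np.einsum("ij,jk,ik->i", C, cov, C))
        z = est / cse
        p_raw = 2 * stats.norm.sf(np.abs(z))

        vcv = C @ cov @ C.T
        corr = vcv / np.outer(cse, cse)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            np.zeros(len(pairs)), corr, size=nsim, method="svd"
        )
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([np.mean(maxabs >= abs(zi)) for zi in z])
        p_adj = np.maximum(p_adj, p_raw)  # adjustment never helps

        return pd.DataFrame(
            {
                "contrast": [f"{a} - {b}" for a, b in pairs],
                "estimate": est,
                "se": cse,
                "z": z,
                "p_unadjusted": p_raw,
                "p_adjusted": p_adj,
            }
        ).set_index("contrast")

    # -- presentation --------------------------------------------------
    def or_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        flags = self.bh_flags()
        return pd.DataFrame(
            {
                "coef": self.params,
                "OR": self.odds_ratios,
                "or_lower": ci["or_lower"],
                "or_upper": ci["or_upper"],
                "p": self.pvalues,
                "bh_significant": flags,
            }
        )

    def summary(self) -> str:
        chi2, df, p = self.lr_test_vs_null()
        lines = [
            f"Logistic outcome model: {self.spec.name}",
            f"  outcome: {self.spec.outcome}   table: {self.spec.scope}   "
            f"observations: {self.nobs}",
            f"  LR vs null: chi2({df}) = {chi2:.1f}, p = {p:.3g}   "
            f"Tjur R2 = {self.tjur_r2():.3f}",
            "",
            f"  {'term':<34}{'OR':>8}{'95% CI':>18}{'p':>9}  BH",
        ]
        table = self.or_table()
        for name, row in table.iterrows():
            ci = f"({row.or_lower:.2f}-{row.or_upper:.2f})"
            star = "*" if row.bh_significant else ""
            lines.append(
                f"  {name:<34}{row.OR:>8.2f}{ci:>18}{row.p:>9.3f}  {star}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        chi2, df, p = self.lr_test_vs_null()
        table = self.or_table()
        return {
            "name": self.spec.name,
            "outcome": self.spec.outcome,
            "scope": self.spec.scope,
            "nobs": self.nobs,
            "lr_chi2": chi2,
            "lr_df": df,
            "lr_p": p,
            "tjur_r2": self.tjur_r2(),
            "terms": {
                name: {
                    "coef": float(row.coef),
                    "or": float(row.OR),
                    "or_ci": [float(row.or_lower), float(row.or_upper)],
                    "p": float(row.p),
                    "bh_significant": bool(row.bh_significant),
                }
                for name, row in table.iterrows()
            },
            "vif": {k: float(v) for k, v in self.vif().items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Stand-alone statistics
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def tjur_r2(fitted_prob: Sequence[float], outcome: Sequence[int]) -> float:
    """Tjur's coefficient of discrimination from fitted probabilities."""
    mu = np.asarray(fitted_prob, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("Tjur R^2 undefined for a one-class outcome")
    return float(mu[y].mean() - mu[~y].mean())


def vif(design: pd.DataFrame | np.ndarray, names: Optional[list[str]] = None
        ) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) for each column of a numeric
    design matrix (intercept excluded from scoring but included in each
    auxiliary regression).  Exactly collinear columns get ``inf``."""
    X = np.asarray(design, dtype=float)
    if names is None:
        names = (
            list(design.columns)
            if isinstance(design, pd.DataFrame)
            else [f"x{j}" for j in range(X.shape[1])]
        )
    out = {}
    n = X.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(names):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        ssr = np.sum(resid**2)
        if sst == 0 or ssr / sst < 1e-12:
            out[name] = np.inf
        else:
            out[name] = 1.0 / (ssr / sst)
    return pd.Series(out)
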