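"""Multinomial logistic models of interval categories.

The contribution of breathing features to predicting the turn-taking
category of an interval is quantified with multinomial logistic regression:
one coefficient vector per non-reference outcome level, Wald 95% confidence
intervals, and McFadden's pseudo-R² (1 − LL/LL₀, with LL₀ the intercept-only
log-likelihood; values of 0.2–0.4 indicate a very good fit for
likelihood-based models).

Predictors enter step-wise, one at a time in a stated order; a predictor is
kept iff it significantly reduces −2 × log-likelihood (likelihood-ratio test
against the χ² distribution with as many degrees of freedom as coefficients
added).  Because duration, amplitude and slope of a breath phase are highly
collinear (slope is their ratio), a declarative screen retains a single
representative per collinear block before fitting.

Model fitting is delegated to :class:`statsmodels` MNLogit (Newton
optimizer); selection, the pseudo-R² and the coefficient-table layout are
assembled here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.discrete.discrete_model import MNLogit
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class ModelFitError(RuntimeError):
    pass


class CollinearDesignError(ValueError):
    pass


@dataclass
class MultinomialFit:
    """A fitted multinomial logistic model.

    ``coefficients`` is a tidy frame with one row per (level, predictor)
    cell for every non-reference level: columns ``level``, ``predictor``,
    ``b``, ``exp_b``, ``ci95_low``, ``ci95_high``, ``p``.
    """

    outcome_levels: list[str]
    reference_level: str
    predictors: list[str]
    coefficients: pd.DataFrame
    loglik: float
    loglik_null: float
    nobs: int

    @property
    def mcfadden_r2(self) -> float:
        if self.loglik_null == 0.0:
            return 0.0
        return 1.0 - self.loglik / self.loglik_null

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients)

    def coefficient(self, level: str, predictor: str) -> float:
        df = self.coefficients
        row = df[(df["level"] == level) & (df["predictor"] == predictor)]
        if row.empty:
            raise KeyError((level, predictor))
        return float(row["b"].iloc[0])


def _design(
    table: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols = ["const"] + list(predictors)
    X = np.column_stack(
        [np.ones(len(table))]
        + [table[p].to_numpy(dtype=float) for p in predictors]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(cols[j])
        raise CollinearDesignError(
            f"rank-deficient design; collinear columns: {bad}"
        )
    return X, cols


def fit_multinomial(
    table: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    reference: str,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> MultinomialFit:
    """Fit a multinomial logistic regression by maximum likelihood.

    Parameters
    ----------
    table : DataFrame
        One row per analyzed interval; no missing values in used columns.
    outcome : str
        Categorical column with at least two levels.
    predictors : sequence of str
        Numeric or boolean predictor columns (may be empty: null model).
    reference : str
        Outcome level carrying no coefficients.
    """
    levels = sorted(table[outcome].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 levels")
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    used = [outcome, *predictors]
    if table[used].isna().any().any():
        raise ValueError("missing values in used columns")

    ordered = [reference] + [l for l in levels if l != reference]
    codes = table[outcome].astype(str).map({l: i for i, l in enumerate(ordered)})
    y = codes.to_numpy(dtype=int)
    X, cols = _design(table, predictors)

    try:
        with warnings.catch_warnings():
            # convergence is checked explicitly below
            warnings.simplefilter("ignore")
            res = MNLogit(y, X).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=False
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ModelFitError(f"model did not converge: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ModelFitError("Newton optimizer did not converge")

    params = np.asarray(res.params)          # (k_pred+1, J-1)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    z = stats.norm.ppf(0.975)

    rows = []
    for j, level in enumerate(ordered[1:]):
        for k, name in enumerate(cols):
            b = params[k, j]
            se = bse[k, j]
            rows.append(
                {
                    "level": level,
                    "predictor": "Intercept" if name == "const" else name,
                    "b": b,
                    "exp_b": float(np.exp(b)),
                    "ci95_low": b - z * se,
                    "ci95_high": b + z * se,
                    "p": pvals[k, j],
                }
            )
    coeffs = pd.DataFrame(rows)

    if predictors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_res = MNLogit(y, np.ones((len(y), 1))).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=False
            )
        ll0 = float(null_res.llf)
    else:
        ll0 = float(res.llf)
    return MultinomialFit(
        outcome_levels=ordered,
        reference_level=reference,
        predictors=list(predictors),
        coefficients=coeffs,
        loglik=float(res.llf),
        loglik_null=ll0,
        nobs=len(table),
    )


def stepwise_select(
    table: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    reference: str,
    alpha: float = 0.05,
) -> tuple[list[str], MultinomialFit]:
    """Forward step-wise predictor selection by −2LL reduction.

    Candidates are tried in the given order; each is kept iff the
    likelihood-ratio statistic 2·(LL_with − LL_without) exceeds the χ²
    critical value at ``alpha`` with df = number of added coefficients
    (one per non-reference level).  Returns the selected predictors and the
    final fit.
    """
    selected: list[str] = []
    current = fit_multinomial(table, outcome, selected, reference)
    for cand in candidates:
        try:
            trial = fit_multinomial(table, outcome, selected + [cand], reference)
        except (CollinearDesignError, ModelFitError):
            continue
        lr = 2.0 * (trial.loglik - current.loglik)
        df = len(trial.outcome_levels) - 1
        if lr > stats.chi2.ppf(1.0 - alpha, df):
            selected.append(cand)
            current = trial
    return selected, current


#: collinear feature blocks and the representative retained from each
DEFAULT_BLOCKS: dict[frozenset, str] = {
    frozenset({"exh_duration_log2s", "exh_amplitude_sv", "exh_slope_sv_per_s"}):
        "exh_slope_sv_per_s",
    frozenset({"inh_duration_log2s", "inh_amplitude_sv", "inh_slope_sv_per_s"}):
        "inh_slope_sv_per_s",
    frozenset({"exh_onset_level", "exh_offset_level"}): "exh_offset_level",
}


def collinearity_screen(
    predictors: Sequence[str],
    blocks: Mapping[frozenset, str] | None = None,
) -> list[str]:
    """Retain one representative per collinear feature block.

    Duration, amplitude and slope of a breath phase are near-deterministic
    functions of one another, as are the onset and offset levels; the
    screen keeps the designated representative (slope; offset level) when
    any block member is present and passes unrelated predictors through
    unchanged, preserving order.
    """
    blocks = DEFAULT_BLOCKS if blocks is None else blocks
    out: list[str] = []
    for p in predictors:
        block = next((b for b in blocks if p in b), None)
        keep = p if block is None else blocks[block]
        if keep not in out:
            out.append(keep)
    return out


# Pre-registered model families: outcome restriction, predictors, reference.
MODEL_FAMILIES: dict[str, dict] = {
    "exhalatory": {
        "categories": ["WSS-INH", "WSS+INH", "BSS-INH", "BSS+INH",
                       "BSO-INH", "BSO+INH"],
        "predictors": ["exh_slope_sv_per_s", "exh_offset_level", "hold_present"],
        "reference": "WSS-INH",
    },
    "inhalatory_all": {
        "categories": ["WSS+INH", "BSS+INH", "BSO+INH", "TT(S)", "TT(O)"],
        "predictors": ["inh_slope_sv_per_s", "inh_offset_level"],
        "reference": "WSS+INH",
    },
    "inhalatory_tt": {
        "categories": ["WSS+INH", "TT(S)", "TT(O)"],
        "predictors": ["inh_slope_sv_per_s", "inh_offset_level",
                       "speech_lag_log2s"],
        "reference": "WSS+INH",
    },
    "silent_cycle": {
        "categories": ["Hold", "Silent", "TT(S)"],
        "predictors": ["inh_amplitude_sv", "inh_duration_log2s"],
        "reference": "Hold",
    },
}


def fit_family(
    table: pd.DataFrame,
    family: str,
    outcome: str = "category",
    stepwise: bool = True,
    alpha: float = 0.05,
) -> MultinomialFit:
    """Fit one of the pre-registered model families on a feature table.

    Rows are restricted to the family's categories with all required
    predictors present and no exclusion flag (when an ``excluded`` column
    exists).  With ``stepwise=True`` predictors enter via
    :func:`stepwise_select`; otherwise all are fitted directly.
    """
    spec = MODEL_FAMILIES[family]
    df = table.copy()
    if "excluded" in df.columns:
        df = df[df["excluded"].fillna("") == ""]
    df = df[df[outcome].isin(spec["categories"])]
    predictors = [p for p in spec["predictors"] if p in df.columns]
    df = df.dropna(subset=[outcome, *predictors])
    if "hold_present" in predictors:
        df = df.assign(hold_present=df["hold_present"].astype(float))
    if stepwise:
        _, fit = stepwise_select(df, outcome, predictors, spec["reference"],
                                 alpha=alpha)
        return fit
    return fit_multinomial(df, outcome, predictors, spec["reference"])


def coefficient_table(fit: MultinomialFit) -> pd.DataFrame:
    """Printable coefficient table: level, predictor, B, exp(B), CI, p."""
    df = fit.coefficients.rename(
        columns={"b": "B", "exp_b": "exp(B)", "ci95_low": "CI95_LL",
                 "ci95_high": "CI95_UL", "p": "p"}
    )
    df.attrs["loglik"] = fit.loglik
    df.attrs["loglik_null"] = fit.loglik_null
    df.attrs["mcfadden_r2"] = fit.mcfadden_r2
    return df
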