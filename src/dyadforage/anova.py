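"""Fully crossed four-factor ANOVA with permutation-calibrated critical F.

The sweep table is a 2^4 factorial in the four interference costs.  For a
response variable, a classical fixed-effects ANOVA yields fifteen F values
(four main effects, six two-way, four three-way and one four-way
interaction, each with one numerator degree of freedom).  Because the
response distributions are far from ANOVA's assumptions, significance is
judged against critical F values obtained by freely permuting the response
over the intact factor design and harvesting the fifteen F values from each
permutation; the critical value per term is the chosen empirical quantile
(95% by default) of its permuted F distribution.

Effects are then classified with the sign legend used for factorial cost
tables: '+' / '-' for a significant monotone increase / decrease when the
involved cost(s) are switched on, '*' for a significant interaction whose
simple effects disagree in direction, 'NS' otherwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd

from .params import COST_NAMES

__all__ = [
    "AnovaResult",
    "anova_terms",
    "design_matrix",
    "factorial_F",
    "permutation_critical_F",
    "classify_directions",
    "permutation_anova",
]


def anova_terms(factors: tuple[str, ...] = COST_NAMES) -> list[tuple[str, ...]]:
    """The fifteen model terms: every non-empty subset of the four factors,
    ordered by interaction degree then factor order."""
    terms = []
    for k in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, k))
    return terms


def _term_label(term: tuple[str, ...]) -> str:
    return ":".join(term)


def design_matrix(table: pd.DataFrame, factors=COST_NAMES):
    """Effect-coded model matrix [intercept | 15 term columns].

    Factors are recoded 0/1 -> -1/+1; an interaction column is the product
    of its factors' codes.  With a balanced 2^4 design the columns are
    mutually orthogonal, so sequential and classical sums of squares agree;
    with unbalanced data (dropped runs) the sequential decomposition in this
    natural order is used.
    """
    codes = {f: 2.0 * np.asarray(table[f], dtype=float) - 1.0 for f in factors}
    for f, c in codes.items():
        uniq = np.unique(c)
        if not np.all(np.isin(uniq, (-1.0, 1.0))):
            raise ValueError(f"factor {f} is not binary 0/1")
    terms = anova_terms(factors)
    cols = [np.ones(len(table))]
    for term in terms:
        col = np.ones(len(table))
        for f in term:
            col = col * codes[f]
        cols.append(col)
    return np.column_stack(cols), terms


def _qr_effects(X: np.ndarray):
    Q, R = np.linalg.qr(X)
    return Q


def factorial_F(table: pd.DataFrame, response: str, factors=COST_NAMES):
    """Fifteen F values of the fully crossed fixed-effects ANOVA.

    Rows with a ``failed`` flag or a non-finite response are excluded
    listwise.  Sums of squares are sequential in the natural term order
    (orthogonal, hence classical, on a balanced table).  Returns
    ``(F, terms, df_error)``.  A constant response yields all-zero F values
    with a warning.
    """
    tab = _clean(table, response)
    y = np.asarray(tab[response], dtype=float)
    X, terms = design_matrix(tab, factors)
    n, p = X.shape
    df_e = n - p
    if df_e <= 0:
        raise ValueError(f"not enough rows ({n}) for {p} model parameters")
    if np.ptp(y) == 0.0:
        warnings.warn(f"response {response!r} is constant; all F set to 0")
        return np.zeros(len(terms)), terms, df_e
    Q = _qr_effects(X)
    eff = Q.T @ y
    ss_terms = eff[1:] ** 2
    sse = float(y @ y - eff @ eff)
    if sse <= 0:
        sse = np.finfo(float).tiny
    F = ss_terms / (sse / df_e)
    return F, terms, df_e


def _clean(table: pd.DataFrame, response: str) -> pd.DataFrame:
    tab = table
    if "failed" in tab.columns:
        tab = tab[~tab["failed"].astype(bool)]
    y = pd.to_numeric(tab[response], errors="coerce")
    return tab[np.isfinite(y)]


def permutation_critical_F(
    table: pd.DataFrame,
    response: str,
    n_perm: int = 50_000,
    q: float = 0.95,
    seed: int = 0,
    factors=COST_NAMES,
    chunk: int = 2_000,
):
    """Per-term empirical critical F by free permutation of the response.

    The response vector is permuted without replacement ``n_perm`` times
    against the intact factor matrix; each permutation yields fifteen F
    values and the q-quantile of each term's permuted distribution is its
    critical value.  Returns ``(critF, terms)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tab = _clean(table, response)
    y = np.asarray(tab[response], dtype=float)
    X, terms = design_matrix(tab, factors)
    n, p = X.shape
    df_e = n - p
    Q = _qr_effects(X)
    yy = float(y @ y)
    rng = np.random.default_rng(seed)
    Fs = np.empty((len(terms), n_perm))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        Y = np.empty((n, m))
        for j in range(m):
            Y[:, j] = rng.permutation(y)
        eff = Q.T @ Y                      # (p, m)
        ss_terms = eff[1:] ** 2
        sse = yy - (eff**2).sum(axis=0)
        sse = np.maximum(sse, np.finfo(float).tiny)
        Fs[:, done:done + m] = ss_terms / (sse / df_e)
        done += m
    crit = np.quantile(Fs, q, axis=1)
    return crit, terms


def _simple_effect_directions(table: pd.DataFrame, response: str, term) -> list[float]:
    """Mean response differences (factor on minus off) for every factor of
    the term, within every combination of the term's other factors."""
    tab = _clean(table, response)
    diffs = []
    for f in term:
        others = [g for g in term if g != f]
        if others:
            groups = tab.groupby(others, sort=True)
        else:
            groups = [((), tab)]
        for _, sub in groups:
            on = sub.loc[sub[f] == 1, response].mean()
            off = sub.loc[sub[f] == 0, response].mean()
            diffs.append(float(on - off))
    return diffs


def classify_directions(
    table: pd.DataFrame,
    response: str,
    F: np.ndarray,
    critF: np.ndarray,
    factors=COST_NAMES,
) -> list[str]:
    """Direction label per term: '+', '-', '*' or 'NS'.

    'NS' when F < critical F.  A significant main effect is '+' or '-' by
    the sign of the marginal (cost on minus cost off) mean difference.  A
    significant interaction is '+' ('-') only when every involved factor's
    simple effect, within every combination of the other involved factors,
    points the same way; otherwise '*'.
    """
    terms = anova_terms(factors)
    labels = []
    for term, f_val, crit in zip(terms, F, critF):
        if not (f_val >= crit):
            labels.append("NS")
            continue
        diffs = _simple_effect_directions(table, response, term)
        if all(d > 0 for d in diffs):
            labels.append("+")
        elif all(d < 0 for d in diffs):
            labels.append("-")
        else:
            labels.append("*" if len(term) > 1 else ("+" if sum(diffs) > 0 else "-"))
    return labels


@dataclasses.dataclass
class AnovaResult:
    """Per-response factorial ANOVA with permutation calibration."""

    response: str
    terms: list
    F: np.ndarray
    critical_F: np.ndarray
    directions: list
    df_error: int
    n_perm: int
    quantile: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": [_term_label(t) for t in self.terms],
            "F": self.F,
            "critical_F": self.critical_F,
            "direction": self.directions,
        })

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": [_term_label(t) for t in self.terms],
            "F": [float(v) for v in self.F],
            "critical_F": [float(v) for v in self.critical_F],
            "directions": list(self.directions),
            "df_error": int(self.df_error),
            "n_perm": int(self.n_perm),
            "quantile": float(self.quantile),
            "seed": int(self.seed),
        }


def permutation_anova(
    table: pd.DataFrame,
    response: str,
    n_perm: int = 50_000,
    q: float = 0.95,
    seed: int = 0,
    factors=COST_NAMES,
) -> AnovaResult:
    """Full pipeline for one response: F values, critical values, labels."""
    F, terms, df_e = factorial_F(table, response, factors)
    crit, _ = permutation_critical_F(table, response, n_perm=n_perm, q=q,
                                     seed=seed, factors=factors)
    directions = classify_directions(table, response, F, crit, factors)
    return AnovaResult(response, terms, F, crit, directions, df_e, n_perm, q, seed)
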