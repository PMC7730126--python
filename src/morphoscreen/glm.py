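"""Factor signatures: GLMs of per-well phenotype proportions.

For each phenotype, the number of colonies of that phenotype in a well is
modelled as a binomial count out of the well's colony total, with a logit
link and the four screen factors (MP stiffness, DG degradability, EC
composition, SF soluble EGF) as categorical predictors.  Dispersion is
estimated from the Pearson chi-square (quasi-binomial), which absorbs the
within-well overdispersion that heterogeneous wells produce.  On top of the
fit: stepwise-AIC selection over two-way interactions, least-squares means
per factor level (marginal predictions averaged over the grid of the other
factors, back-transformed to the proportion scale with delta-method
standard errors) and Tukey–Kramer adjusted pairwise level contrasts.

A linear-on-frequency variant (identity link on the observed per-well
frequency) is available via ``family="linear"`` for comparability with
classical least-squares treatments of proportion data.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import studentized_range

from .effects import PHENOTYPES

log = logging.getLogger(__name__)

__all__ = [
    "PhenotypeGLM",
    "PhenotypeGLMResults",
    "FACTORS",
    "significance_code",
    "two_way_scope",
]

#: profile-table column per screen factor
FACTORS = ("stiffness_kPa", "degradability", "ecm", "egf")
_SHORT = {"stiffness_kPa": "mp", "degradability": "dg", "ecm": "ec", "egf": "sf"}


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_way_scope(factors: tuple[str, ...] = FACTORS) -> list[str]:
    """All two-way interaction terms among the screen factors."""
    return [f"{a}:{b}" for a, b in itertools.combinations(factors, 2)]


def _rhs(terms: list[str]) -> str:
    parts = []
    for t in terms:
        parts.append(":".join(f"C({f})" for f in t.split(":")))
    return " + ".join(parts) if parts else "1"


class PhenotypeGLM:
    """Model of one phenotype's per-well proportion against the screen factors.

    Parameters
    ----------
    profiles : DataFrame
        One row per well with factor columns (``stiffness_kPa``,
        ``degradability``, ``ecm``, ``egf``), ``n_colonies`` and either the
        phenotype count column ``n_<phenotype>`` or the frequency column
        ``f_<phenotype>``.
    phenotype : str
        One of the four phenotype names.
    terms : list of str, optional
        Model terms over factor-column names, e.g.
        ``["stiffness_kPa", "egf", "stiffness_kPa:egf"]``.  Defaults to the
        four main effects.
    family : {"binomial", "linear"}
        Binomial-logit on counts (default) or linear on frequencies.
    """

    def __init__(
        self,
        profiles: pd.DataFrame,
        phenotype: str,
        terms: list[str] | None = None,
        family: str = "binomial",
    ):
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        if family not in ("binomial", "linear"):
            raise ValueError("family must be 'binomial' or 'linear'")
        self.phenotype = phenotype
        self.family = family
        self.terms = list(terms) if terms is not None else list(FACTORS)
        data = profiles.copy()
        empty = data["n_colonies"] <= 0
        if empty.any():
            log.warning("excluding %d wells with zero colonies", int(empty.sum()))
        self.excluded_wells = list(data.loc[empty, "well_id"]) \
            if "well_id" in data else []
        data = data.loc[~empty].reset_index(drop=True)
        count_col = f"n_{phenotype}"
        if count_col not in data:
            data[count_col] = np.round(
                data[f"f_{phenotype}"] * data["n_colonies"]
            ).astype(int)
        for f in FACTORS:
            if f in data and data[f].nunique() < 1:
                raise ValueError(f"factor {f} has no levels in the data")
        data["_success"] = data[count_col].astype(float)
        data["_failure"] = (data["n_colonies"] - data[count_col]).astype(float)
        data["_freq"] = data["_success"] / data["n_colonies"]
        self.data = data

    # -- fitting ---------------------------------------------------------

    def _design(self, terms: list[str]):
        X = patsy.dmatrix(_rhs(terms), self.data, return_type="dataframe")
        return X

    def fit(self, terms: list[str] | None = None) -> "PhenotypeGLMResults":
        terms = list(terms) if terms is not None else self.terms
        X = self._design(terms)
        separation_flag = False
        if self.family == "binomial":

            def _quasi_fit(endog):
                # fit, then rescale by the Pearson dispersion computed on the
                # count scale (fit(scale="X2") would use per-proportion
                # residuals that ignore the binomial totals)
                model = sm.GLM(endog, X, family=sm.families.Binomial())
                res = model.fit()
                disp = (
                    float(res.pearson_chi2 / res.df_resid)
                    if res.df_resid > 0 else 1.0
                )
                return model.fit(scale=max(disp, 1e-8))

            endog = self.data[["_success", "_failure"]].to_numpy()
            res = _quasi_fit(endog)
            if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 15:
                # (quasi-)separation: continuity-correct the counts and refit
                separation_flag = True
                log.warning(
                    "%s: separation detected; refitting with 0.5 count "
                    "correction", self.phenotype,
                )
                res = _quasi_fit(endog + 0.5)
        else:
            model = sm.OLS(self.data["_freq"].to_numpy(), X)
            res = model.fit()
        return PhenotypeGLMResults(self, res, X, terms, separation_flag)

    # -- model selection -------------------------------------------------

    def _aic(self, terms: list[str]) -> float:
        X = self._design(terms)
        if self.family == "binomial":
            endog = self.data[["_success", "_failure"]].to_numpy()
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        else:
            res = sm.OLS(self.data["_freq"].to_numpy(), X).fit()
        return float(res.aic)

    def step_aic(
        self, scope: list[str] | None = None, forced: list[str] | None = None
    ) -> tuple["PhenotypeGLMResults", list[dict]]:
        """Greedy bidirectional stepwise search over interaction terms.

        Main effects are forced in; candidate terms from ``scope`` (default:
        all two-way interactions) are added or removed one at a time,
        accepting the move that most improves the (binomial-likelihood) AIC,
        until no move improves it.  Returns the refitted best model (with
        quasi-binomial dispersion) and the search trace.
        """
        forced = list(forced) if forced is not None else list(FACTORS)
        scope = list(scope) if scope is not None else two_way_scope()
        current: list[str] = []
        best_aic = self._aic(forced)
        trace = [{"action": "start", "term": None, "aic": best_aic}]
        while True:
            moves = [("add", t) for t in scope if t not in current]
            moves += [("drop", t) for t in current]
            best_move, best_move_aic = None, best_aic
            for action, term in moves:
                cand = (
                    current + [term] if action == "add"
                    else [t for t in current if t != term]
                )
                aic = self._aic(forced + cand)
                if aic < best_move_aic - 1e-9:
                    best_move, best_move_aic = (action, term), aic
            if best_move is None:
                break
            action, term = best_move
            current = (
                current + [term] if action == "add"
                else [t for t in current if t != term]
            )
            best_aic = best_move_aic
            trace.append({"action": action, "term": term, "aic": best_aic})
        return self.fit(forced + current), trace


class PhenotypeGLMResults:
    """Fitted phenotype GLM with marginal-means and contrast machinery."""

    def __init__(self, model: PhenotypeGLM, res, X: pd.DataFrame,
                 terms: list[str], separation: bool):
        self.model = model
        self.res = res
        self.X = X
        self.terms = terms
        self.separation = separation

    # -- basic accessors -------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return self.res.params

    @property
    def dispersion(self) -> float:
        return float(getattr(self.res, "scale", 1.0))

    @property
    def df_resid(self) -> float:
        return float(self.res.df_resid)

    def fitted_proportions(self) -> np.ndarray:
        if self.model.family == "binomial":
            return np.asarray(self.res.mu)
        return np.asarray(self.res.fittedvalues)

    def _link(self, p):
        return np.log(p / (1 - p)) if self.model.family == "binomial" else p

    def _inverse(self, eta):
        return expit(eta) if self.model.family == "binomial" else eta

    # -- inference -------------------------------------------------------

    def _term_slice(self, factor: str):
        info = self.X.design_info
        name = f"C({factor})"
        for term, sl in info.term_name_slices.items():
            if term == name:
                return sl
        raise KeyError(f"factor {factor!r} not a main-effect term of this model")

    def factor_wald(self, factor: str) -> dict:
        """Joint Wald test (F form, quasi-dispersion) that a factor has no effect."""
        sl = self._term_slice(factor)
        k = self.X.shape[1]
        idx = range(*sl.indices(k))
        R = np.zeros((len(list(idx)), k))
        for r, j in enumerate(range(*sl.indices(k))):
            R[r, j] = 1.0
        test = self.res.wald_test(R, use_f=True, scalar=False)
        return {
            "factor": factor,
            "statistic": float(np.squeeze(test.statistic)),
            "p_value": float(np.squeeze(test.pvalue)),
            "df_num": int(R.shape[0]),
            "df_den": float(self.df_resid),
        }

    def _grid(self) -> pd.DataFrame:
        levels = {f: sorted(self.model.data[f].unique()) for f in FACTORS}
        rows = list(itertools.product(*levels.values()))
        return pd.DataFrame(rows, columns=list(levels))

    def _lsmean_rows(self, factor: str) -> tuple[list, np.ndarray]:
        """Averaged design rows per level of ``factor`` over the full grid."""
        grid = self._grid()
        if factor not in grid.columns:
            raise KeyError(f"unknown factor {factor!r}")
        (M,) = patsy.build_design_matrices([self.X.design_info], grid)
        M = np.asarray(M)
        levels, L = [], []
        for lv, idx in grid.groupby(factor).groups.items():
            levels.append(lv)
            L.append(M[np.asarray(idx)].mean(axis=0))
        return levels, np.vstack(L)

    def ls_means(self, factor: str) -> pd.DataFrame:
        """Least-squares mean proportion (with SE) for each level of a factor.

        Predictions on the link scale are averaged over the level grid of the
        other factors, then back-transformed; SEs use the delta method.
        """
        observed = set(self.model.data[factor].unique())
        levels, L = self._lsmean_rows(factor)
        beta = np.asarray(self.res.params)
        cov = np.asarray(self.res.cov_params())
        eta = L @ beta
        se_eta = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
        p = self._inverse(eta)
        se_p = se_eta * p * (1 - p) if self.model.family == "binomial" else se_eta
        counts = self.model.data.groupby(factor)["well_id"].count() \
            if "well_id" in self.model.data else None
        rows = []
        for lv, e, s, pp, sp in zip(levels, eta, se_eta, p, se_p):
            if lv not in observed:
                raise KeyError(f"level {lv!r} absent from the data")
            rows.append(
                {"factor": factor, "level": lv, "ls_mean": float(pp),
                 "se": float(sp), "link_estimate": float(e),
                 "link_se": float(s),
                 "n_wells": int(counts[lv]) if counts is not None else -1}
            )
        return pd.DataFrame(rows)

    def tukey_kramer(self, factor: str) -> pd.DataFrame:
        """All pairwise level contrasts with studentized-range adjusted p.

        The Tukey–Kramer statistic for a pair is q = |diff| * sqrt(2) / SE,
        with the pair's own (unequal-n) standard error on the link scale,
        referred to the studentized range with k = number of levels and the
        model's residual degrees of freedom.  For a two-level factor this
        reduces to the unadjusted two-sided test.
        """
        levels, L = self._lsmean_rows(factor)
        k = len(levels)
        if k < 2:
            raise ValueError("factor needs at least 2 levels")
        beta = np.asarray(self.res.params)
        cov = np.asarray(self.res.cov_params())
        eta = L @ beta
        p = self._inverse(eta)
        df = max(self.df_resid, 1.0)
        rows = []
        for i, j in itertools.combinations(range(k), 2):
            c = L[i] - L[j]
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            if se == 0:
                padj = np.nan
            else:
                q = abs(diff) * np.sqrt(2.0) / se
                padj = float(np.clip(studentized_range.sf(q, k, df), 0.0, 1.0))
            rows.append(
                {
                    "factor": factor, "levelA": levels[i], "levelB": levels[j],
                    "estimate": float(p[i] - p[j]), "link_estimate": diff,
                    "se": se, "p_adj": padj, "code": significance_code(padj)
                    if np.isfinite(padj) else "",
                }
            )
        return pd.DataFrame(rows)

    def signature(self) -> dict[str, pd.DataFrame]:
        """Per-factor LS-means and Tukey–Kramer contrast tables."""
        return {
            f: {"ls_means": self.ls_means(f), "contrasts": self.tukey_kramer(f)}
            for f in FACTORS if f in self.terms
        }

    def summary(self) -> str:
        lines = [
            f"Phenotype proportion GLM — {self.model.phenotype} "
            f"({self.model.family})",
            f"terms: {' + '.join(self.terms)}",
            f"n wells: {len(self.model.data)}   "
            f"dispersion: {self.dispersion:.3f}   "
            f"df_resid: {self.df_resid:.0f}"
            + ("   [separation-corrected]" if self.separation else ""),
            "",
            "Factor Wald tests (quasi-binomial F):"
            if self.model.family == "binomial" else "Factor F tests:",
        ]
        for f in FACTORS:
            if f not in self.terms:
                continue
            w = self.factor_wald(f)
            lines.append(
                f"  {f:<16s} F = {w['statistic']:8.3f}  "
                f"p = {w['p_value']:.3g} {significance_code(w['p_value'])}"
            )
        lines.append("")
        for f in FACTORS:
            if f not in self.terms:
                continue
            lines.append(f"LS-means — {f}:")
            for row in self.ls_means(f).itertuples(index=False):
                lines.append(
                    f"  {str(row.level):<8s} {row.ls_mean:7.4f} ± {row.se:.4f}"
                )
        return "\n".join(lines)
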