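"""AICc multimodel inference: candidate sets, weights, model-averaged effects.

Candidate generalized linear mixed models (random intercept per animal) are
fitted by ML to a derived response (log UD area, log haul-out distance, or
logit dive focus), ranked by small-sample AIC (AICc), and the models holding
95% of the AICc weight are averaged: each term's coefficient is the
weight-renormalized mean over the selected models containing it, with
unconditional (between-model) standard errors and normal 95% CIs. A CI
excluding zero marks a significant effect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mixedlm import LMMFit, fit_lmm

MAIN_TERMS = ("species", "month", "sex", "mass")
INTERACTION = "species:month"

#: Residual correlation structure per analysis: UD areas are one value per
#: animal-month (independence), haul-out distances are serially correlated
#: (discrete AR1), dive metrics repeat every 6 hr at unequal spacing
#: (continuous-time AR1 by time within animal).
ANALYSIS_CORRELATION = {"ud": "none", "distance": "ar1", "dive": "car1"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: additive fixed terms (+ optional interaction)."""

    terms: tuple
    correlation: str = "none"

    def __post_init__(self):
        if INTERACTION in self.terms and not {"species", "month"} <= set(self.terms):
            raise ValueError("species:month requires both main effects")

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "null"


@dataclass
class FittedModel:
    """A fitted candidate: coefficients, likelihood, AICc bookkeeping."""

    spec: ModelSpec
    coef: dict                  # coefficient name -> estimate
    se: dict
    loglik: float
    k: int
    n: int
    aicc: float = field(default=np.nan)
    usable: bool = True


@dataclass
class AveragedEstimate:
    term: str
    beta: float
    ci_lower: float
    ci_upper: float
    significant: bool


def build_candidate_set(analysis: str) -> list[ModelSpec]:
    """Deterministic enumeration of the candidate set for one analysis.

    ``ud`` and ``dive``: null + four single-term models + all additive
    combinations of the four main effects + the species-month interaction
    added to every model containing both mains. ``distance``: null + four
    singles + all two- and three-term additive combinations (no interaction).
    """
    if analysis not in ANALYSIS_CORRELATION:
        raise ValueError(f"unknown analysis {analysis!r}; "
                         f"expected one of {sorted(ANALYSIS_CORRELATION)}")
    corr = ANALYSIS_CORRELATION[analysis]
    max_terms = 3 if analysis == "distance" else 4
    specs = [ModelSpec((), corr)]
    for r in range(1, max_terms + 1):
        for combo in itertools.combinations(MAIN_TERMS, r):
            specs.append(ModelSpec(combo, corr))
            if analysis != "distance" and {"species", "month"} <= set(combo):
                specs.append(ModelSpec(combo + (INTERACTION,), corr))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc_weights(aicc_values) -> np.ndarray:
    """Akaike weights: exp(-delta/2) normalized over the model set."""
    a = np.asarray(aicc_values, float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def transform_response(y, kind: str | None, n_trials=None):
    """Response transformation: ``log``, ``logit`` (with boundary clip) or None.

    The logit clip bounds proportions to ``[1/(4N), 1 - 1/(4N)]`` per row
    (``n_trials``), since focus values of exactly 0 or 1 occur in the data.
    """
    y = np.asarray(y, float)
    if kind is None:
        return y
    if kind == "log":
        if np.any(y <= 0):
            raise ValueError("log transform needs positive responses")
        return np.log(y)
    if kind == "logit":
        if n_trials is None:
            raise ValueError("logit transform needs n_trials for the boundary clip")
        n_trials = np.asarray(n_trials, float)
        eps = 1.0 / (4.0 * np.maximum(n_trials, 2.0))
        p = np.clip(y, eps, 1.0 - eps)
        return np.log(p / (1.0 - p))
    raise ValueError(f"unknown transform {kind!r}")


def _month_levels(series: pd.Series) -> list:
    """Month levels with September first (the reference level)."""
    levels = sorted(set(series))
    if 9 in levels:
        levels = [9] + [m for m in levels if m != 9]
    return levels


def design_matrix(data: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    """Treatment-coded design matrix for the given fixed terms.

    species/sex/month are categorical (month reference = September); mass is
    numeric and centered; the species:month interaction is the product of the
    two dummy sets.
    """
    n = len(data)
    cols, names = [np.ones(n)], ["(Intercept)"]

    def _dummies(col, levels=None):
        s = data[col]
        levels = sorted(set(s)) if levels is None else levels
        out = []
        for lev in levels[1:]:
            out.append(((s == lev).to_numpy(float), f"{col}[{lev}]"))
        return out

    dummy_cache = {}
    for term in terms:
        if term == "mass":
            m = data["mass"].to_numpy(float)
            cols.append(m - m.mean())
            names.append("mass")
        elif term == "month":
            dummy_cache[term] = _dummies("month", _month_levels(data["month"]))
            for v, nm in dummy_cache[term]:
                cols.append(v)
                names.append(nm)
        elif term in ("species", "sex"):
            dummy_cache[term] = _dummies(term)
            for v, nm in dummy_cache[term]:
                cols.append(v)
                names.append(nm)
        elif term == INTERACTION:
            for vs, ns in dummy_cache["species"]:
                for vm, nm in dummy_cache["month"]:
                    cols.append(vs * vm)
                    names.append(f"{ns}:{nm}")
        else:
            raise ValueError(f"unknown model term {term!r}")
    return np.column_stack(cols), names


def fit_candidates(data: pd.DataFrame, specs: list[ModelSpec], response: str,
                   transform: str | None = None, n_trials_col: str | None = None,
                   group_col: str = "animal_id",
                   time_col: str | None = None) -> list[FittedModel]:
    """Fit every candidate model; non-converging models are dropped.

    The response transformation is applied before fitting; observation times
    (``time_col``, hours or any consistent unit) are required for the
    continuous-time AR1 structure.
    """
    y = transform_response(
        data[response], transform,
        data[n_trials_col] if n_trials_col else None)
    groups = data[group_col].to_numpy()
    times = None
    if time_col is not None:
        t = data[time_col]
        times = (pd.to_datetime(t).astype("int64").to_numpy() / 1e9 / 3600.0
                 if not np.issubdtype(t.dtype, np.number) else t.to_numpy(float))
    fits = []
    for spec in specs:
        X, names = design_matrix(data, spec.terms)
        if spec.correlation == "car1" and times is None:
            raise ValueError("car1 correlation needs time_col")
        try:
            fit: LMMFit = fit_lmm(y, X, groups, times, spec.correlation)
        except Exception as exc:              # noqa: BLE001 - drop and log
            warnings.warn(f"model {spec.name!r} failed to fit: {exc}")
            continue
        fm = FittedModel(
            spec=spec,
            coef=dict(zip(names, fit.beta)),
            se=dict(zip(names, fit.se)),
            loglik=fit.loglik, k=fit.k, n=fit.n)
        try:
            fm.aicc = aicc(fm.loglik, fm.k, fm.n)
        except ValueError:
            fm.usable = False
            warnings.warn(f"model {spec.name!r}: AICc undefined (n <= k+1)")
        fits.append(fm)
    return fits


def model_average(fits: list[FittedModel], coverage: float = 0.95,
                  z: float = 1.96) -> dict[str, AveragedEstimate]:
    """Average coefficients over the top models holding ``coverage`` weight.

    Models are ranked by AICc weight; the smallest prefix with cumulative
    weight >= ``coverage`` is kept and its weights renormalized. Each
    coefficient is averaged over the selected models containing it (natural
    averaging, weights renormalized again within those models) with
    unconditional standard errors
    ``SE = sum_i w_i sqrt(SE_i^2 + (beta_i - beta_bar)^2)``.
    """
    usable = [f for f in fits if f.usable]
    if not usable:
        raise ValueError("no usable fitted models")
    w = aicc_weights([f.aicc for f in usable])
    order = np.argsort(-w, kind="stable")
    csum = np.cumsum(w[order])
    n_sel = int(np.searchsorted(csum, coverage - 1e-12) + 1)
    sel = [usable[i] for i in order[:n_sel]]
    w_sel = w[order[:n_sel]]
    w_sel = w_sel / w_sel.sum()

    terms = []
    for f in sel:
        for name in f.coef:
            if name not in terms:
                terms.append(name)
    out = {}
    for term in terms:
        ws, betas, ses = [], [], []
        for f, wi in zip(sel, w_sel):
            if term in f.coef:
                ws.append(wi)
                betas.append(f.coef[term])
                ses.append(f.se[term])
        ws = np.asarray(ws) / np.sum(ws)
        betas = np.asarray(betas)
        ses = np.asarray(ses)
        beta_bar = float(np.sum(ws * betas))
        se_bar = float(np.sum(ws * np.sqrt(ses ** 2 + (betas - beta_bar) ** 2)))
        lo, hi = beta_bar - z * se_bar, beta_bar + z * se_bar
        out[term] = AveragedEstimate(term, beta_bar, lo, hi,
                                     significant=bool(lo > 0 or hi < 0))
    return out


def selection_table(fits: list[FittedModel]) -> pd.DataFrame:
    """Model-selection table: model, k, AICc, delta, weight (sorted)."""
    usable = [f for f in fits if f.usable]
    w = aicc_weights([f.aicc for f in usable])
    tab = pd.DataFrame({
        "model": [f.spec.name for f in usable],
        "k": [f.k for f in usable],
        "loglik": [f.loglik for f in usable],
        "AICc": [f.aicc for f in usable],
        "weight": w,
    }).sort_values("AICc", ignore_index=True)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    return tab[["model", "k", "loglik", "AICc", "delta_AICc", "weight"]]


class AICcModelAverager(BaseEstimator):
    """Candidate-set fitting + AICc model averaging as one sklearn estimator.

    Fitted attributes: ``fits_`` (list of :class:`FittedModel`),
    ``selection_table_`` and ``averaged_`` (term -> :class:`AveragedEstimate`,
    also as DataFrame ``averaged_table_``).
    """

    def __init__(self, analysis: str = "dive", response: str = "dive_focus",
                 transform: str | None = "logit",
                 n_trials_col: str | None = None,
                 group_col: str = "animal_id", time_col: str | None = None,
                 coverage: float = 0.95):
        self.analysis = analysis
        self.response = response
        self.transform = transform
        self.n_trials_col = n_trials_col
        self.group_col = group_col
        self.time_col = time_col
        self.coverage = coverage

    def fit(self, X: pd.DataFrame, y=None):
        specs = build_candidate_set(self.analysis)
        self.fits_ = fit_candidates(
            X, specs, self.response, self.transform, self.n_trials_col,
            self.group_col, self.time_col)
        self.selection_table_ = selection_table(self.fits_)
        self.averaged_ = model_average(self.fits_, self.coverage)
        self.averaged_table_ = pd.DataFrame(
            [(a.term, a.beta, a.ci_lower, a.ci_upper, a.significant)
             for a in self.averaged_.values()],
            columns=["term", "beta", "ci_lower", "ci_upper", "significant"])
        return self
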