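"""Regression-based decomposition of the concentration index.

A logistic model links the binary ill-health outcome H to regressors x_k.
Writing β_k for the average marginal effect of x_k, x̄_k for its weighted
mean and H̄ for the mean outcome, the concentration index decomposes as

    C = Σ_k ζ_k C_k + residual,      ζ_k = β_k x̄_k / H̄,

where C_k is the concentration index of regressor x_k against the *same*
living-standard ranking as the outcome, ζ_k is the elasticity of the mean
outcome with respect to x_k, and the residual (the generalized
concentration of the model error over H̄) is obtained as the remainder
C − Σ ζ_k C_k so that the adding-up identity holds exactly.

The module exposes both a functional surface (:func:`fit_logit`,
:func:`average_marginal_effects`, :func:`decompose`,
:func:`odds_ratio_table`) and a statsmodels-style model object
(:class:`WagstaffModel` whose :meth:`~WagstaffModel.fit` returns a
:class:`WagstaffResults`).
"""
from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import CIResult, concentration_index
from .survey import (
    ConfigError,
    DataError,
    DesignMatrix,
    RankedOutcome,
    SurveyDataset,
    encode_covariates,
)

__all__ = [
    "LogisticFit",
    "DecompositionRow",
    "DecompositionTable",
    "fit_logit",
    "average_marginal_effects",
    "decompose",
    "odds_ratio_table",
    "WagstaffModel",
    "WagstaffResults",
]

_SEPARATION_BOUND = 20.0  # |logit coefficient| beyond this signals separation


@dataclass
class LogisticFit:
    """Weighted maximum-likelihood logit fit.

    ``params`` includes the intercept under the label ``"const"``;
    ``fitted`` are in-sample probabilities.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    aic: float
    converged: bool
    column_names: list[str]

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)


def fit_logit(design: DesignMatrix, outcome, weight=None) -> LogisticFit:
    """Fit the weighted logistic outcome model by maximum likelihood.

    Raises on a rank-deficient design (naming the collinear columns), a
    one-class outcome, or apparent separation (diverging coefficients).
    Convergence tolerance 1e-8, at most 100 iterations.
    """
    y = np.asarray(outcome, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise DataError("logit outcome must be binary 0/1")
    if len(classes) < 2:
        raise DataError("outcome has a single class; the logit is not identified")
    X = sm.add_constant(design.to_frame(), has_constant="add")
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < X.shape[1]:
        _, R = np.linalg.qr(Xv)
        diag = np.abs(np.diag(R))
        bad = [c for c, d in zip(X.columns, diag) if d < 1e-8 * diag.max()]
        raise DataError(f"design matrix is rank deficient; collinear set: {bad}")
    if weight is None:
        w = np.ones(y.size)
    else:
        w = np.asarray(weight, dtype=float)
        w = w / w.mean()  # mean-1 scaling keeps the effective n at face value
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    if np.abs(res.params.to_numpy()).max() > _SEPARATION_BOUND:
        raise DataError(
            "apparent separation (a coefficient diverged); consider merging "
            "sparse categories")
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        aic=float(res.aic),
        converged=bool(res.converged),
        column_names=list(design.column_names),
    )


def average_marginal_effects(fit: LogisticFit, design: DesignMatrix,
                             weight=None, kind: str = "derivative") -> pd.Series:
    """Average marginal effects of every design column.

    ``kind="derivative"`` applies the logit derivative uniformly:
    ``AME_k = β_k Σ_i ŵ_i p_i (1 − p_i)``, which keeps the decomposition
    linear in the regressors and treats dummies and continuous columns
    alike.  ``kind="discrete"`` instead computes the weighted average
    discrete change p(x_k = 1) − p(x_k = 0) for dummy columns.
    """
    if not fit.converged:
        raise DataError("logit fit did not converge; refusing marginal effects")
    if kind not in ("derivative", "discrete"):
        raise ConfigError(f"unknown AME kind {kind!r}")
    n = design.n
    if weight is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weight, dtype=float)
        w = w / w.sum()
    p = fit.fitted
    scale = float(w @ (p * (1.0 - p)))
    ames = {}
    beta = fit.params
    for name in design.column_names:
        col = design.column(name)
        is_dummy = set(np.unique(col)) <= {0.0, 1.0}
        if kind == "discrete" and is_dummy:
            eta = np.log(p / (1 - p))
            b = float(beta[name])
            p1 = 1 / (1 + np.exp(-(eta + b * (1 - col))))
            p0 = 1 / (1 + np.exp(-(eta - b * col)))
            ames[name] = float(w @ (p1 - p0))
        else:
            ames[name] = float(beta[name]) * scale
    return pd.Series(ames)


@dataclass
class DecompositionRow:
    """One regressor's line of the decomposition table."""

    label: str
    group: str
    ame: float
    mean_x: float
    elasticity: float
    ci_k: float
    contribution: float
    percent: float


@dataclass
class DecompositionTable:
    """Concentration-index decomposition for one wave.

    ``explained`` is the sum of the per-regressor contributions ζ_k C_k,
    ``residual`` the remainder C − explained, so
    ``explained + residual == total_ci`` exactly and the percent columns
    sum to 100 exactly.
    """

    rows: list[DecompositionRow]
    total_ci: float
    explained: float
    residual: float
    percent_explained: float
    percent_residual: float
    mean_h: float
    weighted: bool = True
    label: str = ""
    reference_map: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"covariate": r.label, "group": r.group, "ame": r.ame,
              "mean_x": r.mean_x, "elasticity": r.elasticity, "ci_k": r.ci_k,
              "contribution": r.contribution, "percent": r.percent}
             for r in self.rows])

    def to_json(self, path=None) -> str:
        payload = {
            "label": self.label,
            "weighted": self.weighted,
            "total_ci": self.total_ci,
            "explained": self.explained,
            "residual": self.residual,
            "percent_explained": self.percent_explained,
            "percent_residual": self.percent_residual,
            "mean_h": self.mean_h,
            "reference_map": self.reference_map,
            "rows": [r.__dict__ for r in self.rows],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DecompositionTable":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        rows = [DecompositionRow(**r) for r in payload.pop("rows")]
        return cls(rows=rows, **payload)

    @classmethod
    def from_components(cls, labels, elasticities, ci_ks, total_ci, *,
                        mean_h=float("nan"), label="", groups=None,
                        ames=None, mean_xs=None, weighted=True,
                        reference_map=None) -> "DecompositionTable":
        """Assemble a table from precomputed elasticity / C_k pairs.

        Useful for worked examples where ζ_k and C_k come from a
        published table rather than being refit from microdata.
        """
        zet = np.asarray(elasticities, dtype=float)
        cik = np.asarray(ci_ks, dtype=float)
        contrib = zet * cik
        explained = float(contrib.sum())
        residual = float(total_ci) - explained
        rows = []
        for i, lab in enumerate(labels):
            rows.append(DecompositionRow(
                label=lab,
                group=(groups or {}).get(lab, lab),
                ame=float(ames[i]) if ames is not None else float("nan"),
                mean_x=float(mean_xs[i]) if mean_xs is not None else float("nan"),
                elasticity=float(zet[i]),
                ci_k=float(cik[i]),
                contribution=float(contrib[i]),
                percent=100.0 * float(contrib[i]) / total_ci,
            ))
        return cls(rows=rows, total_ci=float(total_ci), explained=explained,
                   residual=residual,
                   percent_explained=100.0 * explained / total_ci,
                   percent_residual=100.0 * residual / total_ci,
                   mean_h=float(mean_h), weighted=weighted, label=label,
                   reference_map=dict(reference_map or {}))


def _build_table(design: DesignMatrix, ames: pd.Series, ranked: RankedOutcome,
                 ci: CIResult, weight, *, label: str = "",
                 weighted: bool = True) -> DecompositionTable:
    n = design.n
    if weight is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weight, dtype=float)
        w = w / w.sum()
    r = ranked.ranks
    r_mean = float(w @ r)
    h_mean = ranked.mean_h
    total_ci = ci.value
    rows: list[DecompositionRow] = []
    for name in design.column_names:
        x = design.column(name)
        x_mean = float(w @ x)
        if x_mean == 0.0:
            warnings.warn(f"regressor {name!r} has zero mean; contribution set to 0",
                          stacklevel=2)
            zeta, ci_k = 0.0, 0.0
        else:
            cov = float(w @ ((x - x_mean) * (r - r_mean)))
            ci_k = 2.0 * cov / x_mean
            zeta = float(ames[name]) * x_mean / h_mean
        contribution = zeta * ci_k
        rows.append(DecompositionRow(
            label=name, group=design.groups.get(name, name),
            ame=float(ames[name]), mean_x=x_mean, elasticity=zeta,
            ci_k=ci_k, contribution=contribution,
            percent=100.0 * contribution / total_ci))
    explained = float(np.sum([row.contribution for row in rows]))
    residual = total_ci - explained
    return DecompositionTable(
        rows=rows, total_ci=total_ci, explained=explained, residual=residual,
        percent_explained=100.0 * explained / total_ci,
        percent_residual=100.0 * residual / total_ci,
        mean_h=h_mean, weighted=weighted, label=label,
        reference_map=dict(design.reference_map))


def decompose(fit: LogisticFit, design: DesignMatrix, ranked: RankedOutcome,
              weight=None, *, ame_kind: str = "derivative",
              label: str = "", weighted: bool | None = None) -> DecompositionTable:
    """Split the outcome's concentration index into regressor contributions.

    Every regressor's concentration index C_k is computed against the
    same fractional-rank vector (and weights) as the outcome's C — the
    regressors are never re-ranked.  A zero-mean regressor contributes 0
    with a warning.  The residual is the remainder C − Σ ζ_k C_k, so the
    adding-up identity is exact by construction.
    """
    if ranked.mean_h <= 0:
        raise DataError("decomposition undefined: mean outcome is zero")
    if weighted is None:
        weighted = weight is not None
    ames = average_marginal_effects(fit, design, weight, kind=ame_kind)
    ci = concentration_index(ranked.outcome, ranks=ranked.ranks, weight=weight,
                             weighted=weighted)
    return _build_table(design, ames, ranked, ci, weight,
                        label=label, weighted=weighted)


def odds_ratio_table(fit: LogisticFit, design: DesignMatrix,
                     schema: dict | None = None) -> pd.DataFrame:
    """Odds ratios with p-values; reference levels rendered as dashes.

    One row per covariate level (reference rows carry ``"-"`` in the
    numeric columns), plus an AIC footer row, mirroring the conventional
    survey-analysis report layout.
    """
    rows = []
    seen_groups: set[str] = set()
    for name in design.column_names:
        group = design.groups.get(name, name)
        if group not in seen_groups and group in design.reference_map:
            rows.append({"covariate": group,
                         "level": design.reference_map[group],
                         "OR": "-", "p_value": "-"})
        seen_groups.add(group)
        level = name[name.index("[") + 1:-1] if "[" in name else ""
        rows.append({
            "covariate": group,
            "level": level,
            "OR": float(np.exp(fit.params[name])),
            "p_value": float(fit.pvalues[name]),
        })
    rows.append({"covariate": "AIC", "level": "", "OR": fit.aic, "p_value": ""})
    return pd.DataFrame(rows)


class WagstaffModel:
    """Concentration-index decomposition model for one survey wave.

    Parameters
    ----------
    dataset : SurveyDataset
        The wave to analyse.
    schema : dict
        Column-mapping schema (see
        :func:`ineqdecomp.survey.load_survey_table`); its ``covariates``
        block drives the dummy encoding.
    weighted : bool
        Use sampling weights throughout (ranking, logit, means, indices).
        ``False`` ignores the weights everywhere, for sensitivity checks.
    ame : {"derivative", "discrete"}
        Average-marginal-effect flavour.

    Examples
    --------
    >>> res = WagstaffModel(dataset, schema).fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, dataset: SurveyDataset, schema: dict, *,
                 weighted: bool = True, ame: str = "derivative") -> None:
        self.dataset = dataset
        self.schema = schema
        self.weighted = weighted
        self.ame_kind = ame
        self.design = encode_covariates(dataset, schema)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: dict,
                       **kwargs) -> "WagstaffModel":
        """Build from a flat per-unit DataFrame laid out like the CSV input."""
        import tempfile

        from .survey import load_survey_table

        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh, index=False)
            path = fh.name
        dataset = load_survey_table(path, schema)
        return cls(dataset, schema, **kwargs)

    @property
    def _weight(self):
        return self.dataset.weight if self.weighted else None

    def fit(self) -> "WagstaffResults":
        w = self._weight
        ranked = RankedOutcome.from_arrays(
            self.dataset.outcome, self.dataset.rank_score, w)
        logit = fit_logit(self.design, self.dataset.outcome, w)
        ames = average_marginal_effects(logit, self.design, w, kind=self.ame_kind)
        ci = concentration_index(self.dataset.outcome, ranks=ranked.ranks,
                                 weight=w, weighted=self.weighted)
        table = _build_table(self.design, ames, ranked, ci, w,
                             label=self.dataset.label, weighted=self.weighted)
        return WagstaffResults(model=self, logit=logit, ames=ames,
                               ranked=ranked, ci=ci, decomposition=table)


@dataclass
class WagstaffResults:
    """Fitted decomposition: logit, marginal effects, indices, table."""

    model: WagstaffModel
    logit: LogisticFit
    ames: pd.Series
    ranked: RankedOutcome
    ci: CIResult
    decomposition: DecompositionTable

    def odds_ratio_table(self) -> pd.DataFrame:
        return odds_ratio_table(self.logit, self.model.design, self.model.schema)

    def summary(self) -> str:
        """Human-readable report: fit diagnostics, C, decomposition table."""
        dec = self.decomposition
        buf = io.StringIO()
        title = dec.label or "ill-health outcome"
        buf.write(f"Concentration-index decomposition — {title}\n")
        buf.write(f"  n = {self.ci.n}, mean outcome = {self.ci.mean_h:.4f}, "
                  f"{'weighted' if self.ci.weighted else 'unweighted'}\n")
        buf.write(f"  C = {self.ci.value:.4f}")
        if self.ci.bounds:
            buf.write(f"  (binary bounds [{self.ci.bounds[0]:.4f}, "
                      f"{self.ci.bounds[1]:.4f}])")
        buf.write(f"\n  logit AIC = {self.logit.aic:.2f}, "
                  f"converged = {self.logit.converged}\n\n")
        frame = dec.to_frame()[["covariate", "elasticity", "ci_k",
                                "contribution", "percent"]]
        buf.write(frame.to_string(index=False,
                                  float_format=lambda v: f"{v:10.4f}"))
        buf.write(f"\n\nExplained  {dec.explained:10.4f}  "
                  f"({dec.percent_explained:7.2f}%)\n")
        buf.write(f"Residual   {dec.residual:10.4f}  "
                  f"({dec.percent_residual:7.2f}%)\n")
        buf.write(f"Total CI   {dec.total_ci:10.4f}  (100.00%)\n")
        return buf.getvalue()
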