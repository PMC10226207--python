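"""Synthetic DHS-like survey generator with known generative structure.

The real microdata motivating this package (national demographic and
health surveys) are access-restricted, so the pipeline is exercised on
simulated mother-level records with a fully known data-generating
process:

* a latent continuous wealth score (standard normal, shifted upward in
  urban strata) that defines the living-standard ranking and its
  quintiles;
* categorical covariates drawn from quintile-conditional probability
  tables (education rising with wealth, distance problems falling, ...);
* a continuous number-of-children covariate (Poisson, rate declining
  with wealth);
* a binary ill-health outcome drawn from a logistic model with known
  coefficients on the dummy-encoded covariates;
* two design strata (urban/rural) with inverse-probability sampling
  weights induced by deliberate urban over/under-sampling.

Two waves with shifted coefficients and covariate gradients emulate the
between-survey contrast (weaker wealth coefficients at the later wave,
i.e. shrinking inequality).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .survey import SurveyDataset

__all__ = [
    "SyntheticSpec",
    "generate_wave",
    "generate_two_waves",
    "closed_form_bottom_share_ci",
    "default_schema",
    "default_baseline_spec",
    "default_followup_spec",
]

QUINTILES = ["poorest", "poorer", "middle", "richer", "richest"]


def _gradient(rows: dict[str, list[float]]) -> dict[str, list[float]]:
    probs = np.array(list(rows.values()), dtype=float)  # levels x quintiles
    if probs.shape[1] != 5:
        raise ValueError("each level needs 5 per-quintile probabilities")
    if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("level probabilities must sum to 1 within each quintile")
    return rows


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic survey wave.

    ``covariate_gradients`` maps a categorical covariate name to a
    ``{level: [P(level | quintile q) for q in poorest..richest]}`` table;
    ``outcome_coefficients`` maps dummy-encoded design labels (e.g.
    ``"education[higher]"``, ``"children"``) to logit coefficients.
    ``target_prevalence``, when set, recalibrates the intercept so the
    expected outcome prevalence hits the target.
    """

    n: int = 4000
    seed: int = 20160211
    label: str = "wave"
    intercept: float = 0.0
    outcome_coefficients: dict[str, float] = field(default_factory=dict)
    covariate_gradients: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    children_rate_by_quintile: list[float] = field(
        default_factory=lambda: [2.8, 2.6, 2.4, 2.2, 1.9])
    urban_sample_share: float = 0.10
    urban_pop_share: float = 0.14
    urban_wealth_shift: float = 0.9
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError("n must be at least 100")
        if not 0 < self.urban_sample_share < 1 or not 0 < self.urban_pop_share < 1:
            raise ValueError("stratum shares must lie in (0, 1)")
        for name, table in self.covariate_gradients.items():
            try:
                _gradient(table)
            except ValueError as exc:
                raise ValueError(f"covariate {name!r}: {exc}") from exc

    def schema_signature(self) -> tuple:
        """Covariate names and levels; waves to be contrasted must match."""
        return tuple(
            (name, tuple(table.keys()))
            for name, table in self.covariate_gradients.items()
        ) + (("children",),)


def closed_form_bottom_share_ci(p: float) -> float:
    """Limiting concentration index when the poorest fraction p holds all
    of the outcome.

    The concentration curve is then L(s) = min(s / p, 1), whose area is
    1 − p/2, giving C = 1 − 2∫L = p − 1 (so p = 0.2 gives −0.8, and
    p → 1 recovers perfect equality).
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    return p - 1.0


def _weighted_quantile_cuts(score: np.ndarray, weight: np.ndarray) -> np.ndarray:
    order = np.argsort(score, kind="mergesort")
    cw = np.cumsum(weight[order])
    cw = cw / cw[-1]
    cuts = []
    for q in (0.2, 0.4, 0.6, 0.8):
        idx = np.searchsorted(cw, q)
        cuts.append(score[order][min(idx, score.size - 1)])
    return np.array(cuts)


def _design_row_probability(spec: SyntheticSpec, covs: pd.DataFrame,
                            quintile: np.ndarray, intercept: float) -> np.ndarray:
    """Linear predictor -> outcome probability under the spec coefficients."""
    eta = np.full(len(covs), intercept)
    for key, beta in spec.outcome_coefficients.items():
        if "[" in key:
            name, level = key[:-1].split("[", 1)
            if name == "wealth":
                x = (np.array(QUINTILES)[quintile] == level).astype(float)
            else:
                x = (covs[name].to_numpy() == level).astype(float)
        else:
            x = covs[key].to_numpy(dtype=float)
        eta = eta + beta * x
    return expit(eta)


def generate_wave(spec: SyntheticSpec) -> SurveyDataset:
    """Draw one synthetic survey wave; byte-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    urban = rng.random(n) < spec.urban_sample_share
    stratum = np.where(urban, "urban", "rural")
    # inverse-probability weight: population share over sample share
    w_urban = spec.urban_pop_share / spec.urban_sample_share
    w_rural = (1 - spec.urban_pop_share) / (1 - spec.urban_sample_share)
    weight = np.where(urban, w_urban, w_rural)
    weight = weight / weight.mean()

    score = rng.normal(0.0, 1.0, n) + spec.urban_wealth_shift * urban
    cuts = _weighted_quantile_cuts(score, weight)
    quintile = np.searchsorted(cuts, score, side="right")

    covs = pd.DataFrame(index=range(n))
    covs["wealth"] = np.array(QUINTILES)[quintile]
    covs["residence"] = stratum
    for name, table in spec.covariate_gradients.items():
        levels = list(table.keys())
        probs = np.array([table[lv] for lv in levels], dtype=float)  # L x 5
        u = rng.random(n)
        cum = np.cumsum(probs[:, quintile], axis=0)  # L x n
        idx = (u[None, :] > cum).sum(axis=0)
        covs[name] = np.array(levels)[idx]
    lam = np.array(spec.children_rate_by_quintile)[quintile]
    covs["children"] = rng.poisson(lam).astype(float)

    intercept = spec.intercept
    if spec.target_prevalence is not None:
        def gap(a: float) -> float:
            p = _design_row_probability(spec, covs, quintile, a)
            return float(np.average(p, weights=weight)) - spec.target_prevalence

        intercept = brentq(gap, -12.0, 12.0, xtol=1e-10)

    p = _design_row_probability(spec, covs, quintile, intercept)
    outcome = (rng.random(n) < p).astype(float)
    if outcome.sum() in (0, n):  # pragma: no cover - pathological specs only
        raise ValueError("degenerate outcome draw; adjust spec coefficients")

    return SurveyDataset(
        outcome=outcome,
        rank_score=score,
        covariates=covs,
        weight=weight,
        stratum_id=stratum,
        psu_id=None,
        label=spec.label,
    )


def generate_two_waves(spec_t1: SyntheticSpec,
                       spec_t: SyntheticSpec) -> tuple[SurveyDataset, SurveyDataset]:
    """Generate an earlier and a later wave with a shared covariate schema."""
    if spec_t1.schema_signature() != spec_t.schema_signature():
        raise ValueError("waves must share the covariate schema "
                         "(same covariates and levels)")
    return generate_wave(spec_t1), generate_wave(spec_t)


def default_schema() -> dict:
    """Column-mapping schema matching the generator's CSV layout."""
    return {
        "outcome": {"column": "outcome"},
        "rank": {"column": "rank_score"},
        "weight": {"column": "weight"},
        "stratum": {"column": "stratum"},
        "covariates": [
            {"name": "wealth", "type": "categorical",
             "levels": QUINTILES, "reference": "poorest"},
            {"name": "education", "type": "categorical",
             "levels": ["none", "primary", "secondary", "higher"],
             "reference": "none"},
            {"name": "residence", "type": "categorical",
             "levels": ["urban", "rural"], "reference": "urban"},
            {"name": "employment", "type": "categorical",
             "levels": ["not_working", "working"], "reference": "not_working"},
            {"name": "distance", "type": "categorical",
             "levels": ["not_a_problem", "problem"],
             "reference": "not_a_problem"},
            {"name": "children", "type": "continuous"},
        ],
    }


_EDU_BASELINE = {
    # P(level | quintile), poorest..richest: schooling rises with wealth
    "none":      [0.62, 0.52, 0.42, 0.30, 0.16],
    "primary":   [0.20, 0.22, 0.22, 0.20, 0.14],
    "secondary": [0.14, 0.20, 0.27, 0.35, 0.40],
    "higher":    [0.04, 0.06, 0.09, 0.15, 0.30],
}
_EDU_FOLLOWUP = {
    "none":      [0.48, 0.40, 0.30, 0.20, 0.10],
    "primary":   [0.22, 0.22, 0.20, 0.17, 0.12],
    "secondary": [0.24, 0.29, 0.36, 0.42, 0.43],
    "higher":    [0.06, 0.09, 0.14, 0.21, 0.35],
}
_EMP_BASELINE = {
    "not_working": [0.22, 0.25, 0.28, 0.32, 0.38],
    "working":     [0.78, 0.75, 0.72, 0.68, 0.62],
}
_EMP_FOLLOWUP = {
    "not_working": [0.32, 0.35, 0.38, 0.42, 0.48],
    "working":     [0.68, 0.65, 0.62, 0.58, 0.52],
}
_DIST_BASELINE = {
    "not_a_problem": [0.28, 0.36, 0.45, 0.55, 0.72],
    "problem":       [0.72, 0.64, 0.55, 0.45, 0.28],
}
_DIST_FOLLOWUP = {
    "not_a_problem": [0.26, 0.33, 0.42, 0.50, 0.66],
    "problem":       [0.74, 0.67, 0.58, 0.50, 0.34],
}

_COEF_BASELINE = {
    "wealth[poorer]": -0.26, "wealth[middle]": -0.45,
    "wealth[richer]": -0.89, "wealth[richest]": -1.47,
    "education[primary]": -0.54, "education[secondary]": -0.89,
    "education[higher]": -1.97,
    "residence[rural]": 0.09,
    "employment[working]": -0.14,
    "distance[problem]": 0.25,
    "children": 0.31,
}
_COEF_FOLLOWUP = {
    # wealth, education and distance gradients flatten at the later wave,
    # so the emulated contrast is one of shrinking socioeconomic inequality
    "wealth[poorer]": -0.29, "wealth[middle]": -0.56,
    "wealth[richer]": -0.71, "wealth[richest]": -0.80,
    "education[primary]": -0.30, "education[secondary]": -0.55,
    "education[higher]": -1.10,
    "residence[rural]": 0.10,
    "employment[working]": -0.29,
    "distance[problem]": 0.11,
    "children": 0.25,
}


def default_baseline_spec(n: int = 4000, seed: int = 20160211) -> SyntheticSpec:
    """Earlier wave: mostly rural sample, steep wealth gradient, prevalence ~0.5."""
    return SyntheticSpec(
        n=n, seed=seed, label="baseline",
        outcome_coefficients=dict(_COEF_BASELINE),
        covariate_gradients={
            "education": _EDU_BASELINE,
            "employment": _EMP_BASELINE,
            "distance": _DIST_BASELINE,
        },
        children_rate_by_quintile=[2.8, 2.6, 2.4, 2.2, 1.9],
        urban_sample_share=0.10, urban_pop_share=0.14,
        target_prevalence=0.50,
    )


def default_followup_spec(n: int = 4000, seed: int = 20160212) -> SyntheticSpec:
    """Later wave: urbanized sample, flatter wealth gradient, prevalence ~0.31."""
    return SyntheticSpec(
        n=n, seed=seed, label="followup",
        outcome_coefficients=dict(_COEF_FOLLOWUP),
        covariate_gradients={
            "education": _EDU_FOLLOWUP,
            "employment": _EMP_FOLLOWUP,
            "distance": _DIST_FOLLOWUP,
        },
        children_rate_by_quintile=[2.4, 2.3, 2.1, 2.0, 1.8],
        urban_sample_share=0.56, urban_pop_share=0.60,
        target_prevalence=0.31,
    )
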