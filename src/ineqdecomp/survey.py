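"""Survey data model: CSV ingestion, dummy encoding, weighted fractional ranks.

The estimation unit throughout the package is one survey respondent (a
mother, in the motivating application) carrying a binary ill-health
outcome, a continuous living-standard score used for ranking, a sampling
weight, and a set of categorical or continuous covariates.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ineqdecomp")

__all__ = [
    "ConfigError",
    "DataError",
    "SurveyDataset",
    "DesignMatrix",
    "RankedOutcome",
    "fractional_rank",
    "load_survey_table",
    "encode_covariates",
]


class ConfigError(ValueError):
    """Schema/configuration problem (bad column mapping, unknown key...)."""


class DataError(ValueError):
    """Data fails a structural requirement (non-binary outcome, zero weight...)."""


def fractional_rank(rank_score, weight=None) -> np.ndarray:
    """Weighted fractional (midpoint) rank by living standard.

    Units are sorted ascending by ``rank_score``; with normalized weights
    ``w_i`` the rank of unit *i* is ``sum(w_j for j before i) + w_i / 2``.
    Units tied on the score are pooled into one block and all receive the
    midpoint rank of the block, which makes downstream indices invariant
    to the row order within ties.  The weighted mean of the returned ranks
    is exactly 0.5.

    Parameters
    ----------
    rank_score : array-like
        Continuous (or ordinal) living-standard score, higher = richer.
    weight : array-like, optional
        Nonnegative sampling weights with positive total.  ``None`` means
        equal weights, in which case the result is the classical midpoint
        rank ``(i - 0.5) / n``.

    Returns
    -------
    numpy.ndarray
        Ranks in the open interval (0, 1), aligned with the input order.
    """
    s = np.asarray(rank_score, dtype=float)
    n = s.size
    if n == 0:
        raise DataError("empty rank_score")
    if weight is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weight, dtype=float)
        if w.shape != s.shape:
            raise DataError("weight and rank_score must have the same length")
        if np.any(w < 0) or not np.isfinite(w).all():
            raise DataError("weights must be finite and nonnegative")
        total = w.sum()
        if total <= 0:
            raise DataError("total weight must be positive")
        w = w / total

    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    w_sorted = w[order]

    if s_sorted[0] == s_sorted[-1]:
        warnings.warn(
            "all rank scores identical; every unit gets rank 0.5 and the "
            "concentration index is degenerate",
            stacklevel=2,
        )
        return np.full(n, 0.5)

    # block boundaries of tied score values in sorted order
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))

    ranks_sorted = np.empty(n)
    cum = 0.0
    for a, b in zip(starts, ends):
        block_w = w_sorted[a:b].sum()
        ranks_sorted[a:b] = cum + block_w / 2.0
        cum += block_w
    ranks = np.empty(n)
    ranks[order] = ranks_sorted
    return ranks


@dataclass
class RankedOutcome:
    """Outcome values paired with weighted fractional ranks.

    Attributes
    ----------
    outcome : numpy.ndarray
        The per-unit outcome H, in input order.
    ranks : numpy.ndarray
        Fractional ranks in (0, 1), weighted mean exactly 0.5.
    mean_h : float
        Weighted mean of the outcome.
    sort_permutation : numpy.ndarray
        Argsort of the ranking score (stable).
    """

    outcome: np.ndarray
    ranks: np.ndarray
    mean_h: float
    sort_permutation: np.ndarray

    @classmethod
    def from_arrays(cls, outcome, rank_score, weight=None) -> "RankedOutcome":
        h = np.asarray(outcome, dtype=float)
        ranks = fractional_rank(rank_score, weight)
        if weight is None:
            mean_h = float(h.mean())
        else:
            w = np.asarray(weight, dtype=float)
            mean_h = float(np.average(h, weights=w))
        perm = np.argsort(np.asarray(rank_score, dtype=float), kind="mergesort")
        return cls(outcome=h, ranks=ranks, mean_h=mean_h, sort_permutation=perm)


@dataclass
class SurveyDataset:
    """One wave of survey microdata, complete cases only.

    ``outcome`` is a binary ill-health indicator (1 = poor utilization),
    ``rank_score`` the continuous living-standard score used for ranking,
    ``covariates`` a column-per-covariate DataFrame (categoricals as
    strings, continuous as floats), ``weight`` nonnegative sampling
    weights.  ``stratum_id`` / ``psu_id`` are optional design labels used
    only for cluster-robust standard errors.
    """

    outcome: np.ndarray
    rank_score: np.ndarray
    covariates: pd.DataFrame
    weight: np.ndarray
    stratum_id: np.ndarray | None = None
    psu_id: np.ndarray | None = None
    label: str = ""
    unweighted: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.rank_score = np.asarray(self.rank_score, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if not set(np.unique(self.outcome)) <= {0.0, 1.0}:
            raise DataError("outcome must be binary 0/1 after recoding")
        if self.n < 2:
            raise DataError("need at least 2 units")
        if np.any(self.weight < 0) or self.weight.sum() <= 0:
            raise DataError("weights must be nonnegative with positive total")
        if len(self.covariates) != self.n:
            raise DataError("covariate table length mismatch")

    @property
    def n(self) -> int:
        return int(self.outcome.size)

    def ranked(self) -> RankedOutcome:
        """Weighted fractional ranking of this wave by living standard."""
        return RankedOutcome.from_arrays(self.outcome, self.rank_score, self.weight)

    def to_dataframe(self, schema: dict | None = None) -> pd.DataFrame:
        """Flat per-unit table (outcome, rank score, weight, covariates)."""
        df = self.covariates.copy()
        df.insert(0, "outcome", self.outcome.astype(int))
        df.insert(1, "rank_score", self.rank_score)
        df["weight"] = self.weight
        if self.stratum_id is not None:
            df["stratum"] = self.stratum_id
        if self.psu_id is not None:
            df["psu"] = self.psu_id
        return df


@dataclass
class DesignMatrix:
    """Dummy-expanded regressor matrix with reference bookkeeping.

    ``column_names`` are ``"covariate[level]"`` for dummies and the bare
    covariate name for continuous regressors; ``groups`` maps each column
    back to its parent covariate (used to aggregate chart output);
    ``reference_map`` records the omitted level per categorical.
    """

    column_names: list[str]
    values: np.ndarray
    reference_map: dict[str, str]
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def weighted_means(self, weight=None) -> pd.Series:
        if weight is None:
            m = self.values.mean(axis=0)
        else:
            w = np.asarray(weight, dtype=float)
            m = (self.values * (w / w.sum())[:, None]).sum(axis=0)
        return pd.Series(m, index=self.column_names)


def _require(condition: bool, exc: type[Exception], message: str) -> None:
    if not condition:
        raise exc(message)


def load_survey_table(path, schema: dict, drop_log=None) -> SurveyDataset:
    """Read one wave of survey microdata from CSV under a column-mapping schema.

    The schema is a plain mapping (typically parsed from YAML)::

        outcome: {column: anc4, ill_level: "no"}
        rank:    {column: wealth_score}
        weight:  {column: wt}            # optional; absent -> unit weights
        stratum: {column: stratum}       # optional
        psu:     {column: psu}           # optional
        covariates:
          - {name: education, type: categorical,
             levels: [none, primary, secondary, higher], reference: none}
          - {name: children, type: continuous}

    A covariate's ``column`` defaults to its ``name``.  Rows with missing
    values in any mapped column are dropped (complete-case analysis) and
    the count is logged; pass ``drop_log`` (a path) to also write a
    one-line JSON record of the exclusions.
    """
    df = pd.read_csv(path)
    _require("outcome" in schema and "rank" in schema, ConfigError,
             "schema must define 'outcome' and 'rank' blocks")
    out_block = schema["outcome"]
    out_col = out_block.get("column")
    _require(out_col is not None, ConfigError, "outcome block needs a 'column'")
    rank_col = schema["rank"].get("column")
    _require(rank_col is not None, ConfigError, "rank block needs a 'column'")

    mapped = [out_col, rank_col]
    weight_col = schema.get("weight", {}).get("column") if schema.get("weight") else None
    if weight_col:
        mapped.append(weight_col)
    stratum_col = schema.get("stratum", {}).get("column") if schema.get("stratum") else None
    psu_col = schema.get("psu", {}).get("column") if schema.get("psu") else None
    for col in (stratum_col, psu_col):
        if col:
            mapped.append(col)
    cov_specs = schema.get("covariates", [])
    cov_cols = {}
    for cov in cov_specs:
        _require("name" in cov, ConfigError, "each covariate needs a 'name'")
        col = cov.get("column", cov["name"])
        cov_cols[cov["name"]] = col
        mapped.append(col)

    missing = [c for c in mapped if c not in df.columns]
    _require(not missing, ConfigError, f"mapped columns absent from CSV: {missing}")

    n_raw = len(df)
    df = df.dropna(subset=mapped)
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d rows", n_dropped, n_raw)
    if drop_log is not None:
        with open(drop_log, "w") as fh:
            json.dump({"rows_read": n_raw, "rows_dropped": n_dropped,
                       "rows_kept": len(df)}, fh)
            fh.write("\n")

    raw_outcome = df[out_col]
    if "ill_level" in out_block:
        outcome = (raw_outcome.astype(str) == str(out_block["ill_level"])).astype(float)
    else:
        outcome = pd.to_numeric(raw_outcome, errors="coerce")
        _require(outcome.notna().all(), DataError,
                 "outcome column is not numeric; declare 'ill_level' to recode")
        _require(set(outcome.unique()) <= {0, 1}, DataError,
                 "outcome must be 0/1 (or declare 'ill_level')")

    if weight_col:
        weight = pd.to_numeric(df[weight_col]).to_numpy(dtype=float)
        unweighted = False
    else:
        weight = np.ones(len(df))
        unweighted = True
    _require(weight.sum() > 0, DataError, "total sampling weight must be positive")

    covariates = pd.DataFrame(index=range(len(df)))
    for cov in cov_specs:
        col = df[cov_cols[cov["name"]]]
        if cov.get("type", "categorical") == "continuous":
            covariates[cov["name"]] = pd.to_numeric(col).to_numpy(dtype=float)
        else:
            covariates[cov["name"]] = col.astype(str).to_numpy()

    return SurveyDataset(
        outcome=outcome.to_numpy(dtype=float),
        rank_score=pd.to_numeric(df[rank_col]).to_numpy(dtype=float),
        covariates=covariates,
        weight=weight,
        stratum_id=df[stratum_col].to_numpy() if stratum_col else None,
        psu_id=df[psu_col].to_numpy() if psu_col else None,
        label=str(schema.get("label", "")),
        unweighted=unweighted,
        n_dropped=n_dropped,
    )


def encode_covariates(data: SurveyDataset, schema: dict) -> DesignMatrix:
    """Dummy-encode the covariates of a wave into a numeric design matrix.

    Categorical covariates contribute one 0/1 column per non-reference
    level, labelled ``"name[level]"``, in schema order then declared level
    order; continuous covariates pass through unchanged under their own
    name.  The reference level must occur in the data.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    refs: dict[str, str] = {}
    groups: dict[str, str] = {}
    for cov in schema.get("covariates", []):
        name = cov["name"]
        series = data.covariates[name]
        if cov.get("type", "categorical") == "continuous":
            values = np.asarray(series, dtype=float)
            cols.append(values)
            names.append(name)
            groups[name] = name
            if np.ptp(values) == 0:
                warnings.warn(f"covariate {name!r} is constant", stacklevel=2)
            continue
        levels = cov.get("levels")
        observed = pd.unique(np.asarray(series, dtype=str))
        if levels is None:
            levels = sorted(observed)
        reference = str(cov.get("reference", levels[0]))
        _require(reference in observed, ConfigError,
                 f"reference level {reference!r} of {name!r} absent from data")
        stray = set(observed) - set(map(str, levels))
        _require(not stray, ConfigError,
                 f"covariate {name!r} has undeclared levels {sorted(stray)}")
        for level in levels:
            level = str(level)
            if level == reference:
                continue
            dummy = (np.asarray(series, dtype=str) == level).astype(float)
            count = int(dummy.sum())
            if count == 0:
                warnings.warn(f"level {level!r} of {name!r} unobserved", stacklevel=2)
            elif count <= 1 or count >= data.n - 1:
                warnings.warn(
                    f"level {level!r} of {name!r} is nearly constant "
                    f"({count}/{data.n} units)", stacklevel=2)
            label = f"{name}[{level}]"
            cols.append(dummy)
            names.append(label)
            groups[label] = name
        refs[name] = reference
    if not cols:
        raise ConfigError("schema declares no covariates")
    return DesignMatrix(
        column_names=names,
        values=np.column_stack(cols),
        reference_map=refs,
        groups=groups,
    )
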