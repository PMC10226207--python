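"""Run configuration, table rendering, and the full-analysis pipeline.

``run_full_analysis`` orchestrates the whole chain for one or two survey
waves: ingestion (or synthetic generation), concentration indices with
standard errors, the logistic odds-ratio table, the per-wave
concentration-index decomposition, the between-wave change decomposition
with its chart, and the concentration-curve overlay.  Outputs land in a
fixed directory layout (``tables/``, ``figures/``, ``logs/``,
``meta.json``) and are byte-stable under a fixed configuration: no
timestamps enter any artifact.
"""
from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import ci_standard_error, concentration_curve, concentration_index
from .oaxaca import contribution_chart, oaxaca
from .survey import ConfigError, SurveyDataset, load_survey_table
from .synthetic import (
    SyntheticSpec,
    default_baseline_spec,
    default_followup_spec,
    default_schema,
)
from .wagstaff import WagstaffModel

__all__ = ["RunConfig", "render_table", "run_full_analysis"]

_KNOWN_OPTIONS = {
    "weighted": bool,
    "ame": str,
    "normalize": str,
    "cluster_se": bool,
    "rounding": int,
    "seed": int,
    "format": str,
}

_SYNTHETIC_BUILDERS = {
    "baseline": default_baseline_spec,
    "followup": default_followup_spec,
}


@dataclass
class RunConfig:
    """Validated analysis configuration (typically parsed from YAML).

    ``waves`` is a list of one or two blocks, each with a ``label`` and
    either a ``path`` to a CSV in the survey schema or a ``synthetic``
    key naming a shipped generator preset (``baseline``/``followup``)
    with optional ``n``/``seed`` overrides.  ``schema`` may be omitted
    when every wave is synthetic.
    """

    waves: list[dict]
    schema: dict
    options: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown_top = set(raw) - {"waves", "schema", "options"}
        if unknown_top:
            raise ConfigError(f"unknown config keys: {sorted(unknown_top)}")
        waves = raw.get("waves")
        if not waves or len(waves) > 2:
            raise ConfigError("config needs one or two 'waves' entries")
        for wave in waves:
            if ("path" in wave) == ("synthetic" in wave):
                raise ConfigError(
                    "each wave needs exactly one of 'path' or 'synthetic'")
            unknown = set(wave) - {"label", "path", "synthetic", "n", "seed"}
            if unknown:
                raise ConfigError(f"unknown wave keys: {sorted(unknown)}")
        options = raw.get("options", {}) or {}
        unknown_opts = set(options) - set(_KNOWN_OPTIONS)
        if unknown_opts:
            raise ConfigError(f"unknown option keys: {sorted(unknown_opts)}")
        for key, value in options.items():
            if not isinstance(value, _KNOWN_OPTIONS[key]):
                raise ConfigError(
                    f"option {key!r} must be {_KNOWN_OPTIONS[key].__name__}")
        schema = raw.get("schema")
        if schema is None:
            if not all("synthetic" in w for w in waves):
                raise ConfigError("'schema' is required when a wave reads a CSV")
            schema = default_schema()
        return cls(waves=waves, schema=schema, options=options)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def option(self, key: str, default):
        return self.options.get(key, default)

    def load_wave(self, index: int) -> SurveyDataset:
        wave = self.waves[index]
        label = str(wave.get("label", f"wave{index + 1}"))
        if "path" in wave:
            schema = dict(self.schema)
            schema["label"] = label
            return load_survey_table(wave["path"], schema)
        preset = wave["synthetic"]
        if isinstance(preset, str):
            if preset not in _SYNTHETIC_BUILDERS:
                raise ConfigError(
                    f"unknown synthetic preset {preset!r}; "
                    f"choose from {sorted(_SYNTHETIC_BUILDERS)}")
            spec: SyntheticSpec = _SYNTHETIC_BUILDERS[preset](
                n=int(wave.get("n", 4000)),
                seed=int(wave.get("seed", self.option("seed", 20160211) + index)),
            )
        else:
            raise ConfigError("'synthetic' must name a preset")
        from .synthetic import generate_wave

        ds = generate_wave(spec)
        ds.label = label
        return ds


def _round_frame(df: pd.DataFrame, digits: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(digits)
    return out


def _to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(map(str, cols)) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines) + "\n"


def render_table(obj, layout: str, fmt: str = "csv", digits: int = 4) -> str:
    """Render a computed table for display or export.

    ``layout`` is one of ``ci``, ``or``, ``wagstaff``, ``oaxaca``;
    ``fmt`` one of ``csv``, ``md``, ``json``.  CSV/markdown round floats
    to ``digits`` decimals; JSON keeps full precision.
    """
    if layout not in ("ci", "or", "wagstaff", "oaxaca"):
        raise ConfigError(f"unknown table layout {layout!r}")
    if fmt == "json":
        if hasattr(obj, "to_json"):
            return obj.to_json()
        return obj.to_json(orient="records", indent=1)
    if layout == "wagstaff":
        frame = obj.to_frame()[["covariate", "elasticity", "ci_k",
                                "contribution", "percent"]]
        footer = pd.DataFrame([
            {"covariate": "Explained", "contribution": obj.explained,
             "percent": obj.percent_explained},
            {"covariate": "Residual", "contribution": obj.residual,
             "percent": obj.percent_residual},
            {"covariate": "CI", "contribution": obj.total_ci, "percent": 100.0},
        ])
        frame = pd.concat([frame, footer], ignore_index=True)
    elif layout == "oaxaca":
        frame = obj.to_frame()[["covariate", "v1_dC", "v1_dZ", "v2_dC",
                                "v2_dZ", "total", "percent"]]
        footer = pd.DataFrame([
            {"covariate": "Explained", "total": obj.explained,
             "percent": obj.percent_explained},
            {"covariate": "Residual", "total": obj.residual_change,
             "percent": obj.percent_residual},
            {"covariate": "Total", "total": obj.delta_ci, "percent": 100.0},
        ])
        frame = pd.concat([frame, footer], ignore_index=True)
    else:
        frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    frame = _round_frame(frame, digits)
    if fmt == "md":
        return _to_markdown(frame)
    if fmt == "csv":
        return frame.to_csv(index=False)
    raise ConfigError(f"unknown format {fmt!r}")


def _ci_table(dataset: SurveyDataset, cluster: bool) -> pd.DataFrame:
    """Weighted and unweighted concentration index with SE, one column per
    wave — the conventional survey-report layout."""
    ranked = dataset.ranked()
    w_ci = concentration_index(dataset.outcome, ranks=ranked.ranks,
                               weight=dataset.weight)
    u_ci = concentration_index(dataset.outcome, dataset.rank_score,
                               weighted=False)
    cluster_id = dataset.psu_id if (cluster and dataset.psu_id is not None) \
        else (dataset.stratum_id if cluster else None)
    se = ci_standard_error(dataset.outcome, ranks=ranked.ranks,
                           weight=dataset.weight, cluster_id=cluster_id)
    return pd.DataFrame({
        "statistic": ["Weighted CI", "Unweighted CI", "Standard Error (S.E.)",
                      "Sample size (N)"],
        dataset.label or "wave": [w_ci.value, u_ci.value, se, dataset.n],
    })


def run_full_analysis(config: RunConfig, outdir) -> dict:
    """Run the whole pipeline and write the report bundle to ``outdir``.

    Returns a dict of the in-memory results (datasets, fitted results,
    change decomposition) for programmatic use.  On any stage failure the
    partially written output directory is removed and the error re-raised
    with the stage name.
    """
    out = Path(outdir)
    stage = "setup"
    log_lines: list[str] = []
    try:
        (out / "tables").mkdir(parents=True, exist_ok=True)
        (out / "figures").mkdir(exist_ok=True)
        (out / "logs").mkdir(exist_ok=True)
        digits = int(config.option("rounding", 4))
        weighted = bool(config.option("weighted", True))
        ame = str(config.option("ame", "derivative"))
        cluster = bool(config.option("cluster_se", False))

        datasets, results = [], []
        ci_frames = []
        for i in range(len(config.waves)):
            stage = f"ingest[{i}]"
            ds = config.load_wave(i)
            datasets.append(ds)
            log_lines.append(json.dumps(
                {"stage": stage, "label": ds.label, "n": ds.n,
                 "dropped": ds.n_dropped, "mean_outcome":
                     round(float(np.average(ds.outcome, weights=ds.weight)), 6)}))
            stage = f"decompose[{i}]"
            res = WagstaffModel(ds, config.schema, weighted=weighted,
                                ame=ame).fit()
            results.append(res)
            log_lines.append(json.dumps(
                {"stage": stage, "label": ds.label,
                 "ci": round(res.ci.value, 6),
                 "explained": round(res.decomposition.explained, 6),
                 "logit_converged": res.logit.converged}))
            ci_frames.append(_ci_table(ds, cluster))
            res.odds_ratio_table().pipe(
                lambda df: df.to_csv(out / "tables" / f"odds_ratios_{ds.label}.csv",
                                     index=False))
            (out / "tables" / f"decomposition_{ds.label}.csv").write_text(
                render_table(res.decomposition, "wagstaff", "csv", digits))
            res.decomposition.to_json(out / "tables" /
                                      f"decomposition_{ds.label}.json")

        stage = "ci-table"
        ci_table = ci_frames[0]
        for extra in ci_frames[1:]:
            ci_table = ci_table.merge(extra, on="statistic")
        ci_table.to_csv(out / "tables" / "concentration_indices.csv", index=False)

        stage = "curves"
        _curves_figure(datasets, out / "figures" / "curves.png",
                       out / "figures" / "curves.csv")

        change = None
        if len(datasets) == 2:
            stage = "oaxaca"
            change = oaxaca(results[1].decomposition, results[0].decomposition)
            (out / "tables" / "oaxaca.csv").write_text(
                render_table(change, "oaxaca", "csv", digits))
            change.to_json(out / "tables" / "oaxaca.json")
            contribution_chart(change, out / "figures" / "oaxaca.png",
                               out / "figures" / "oaxaca.csv")
            log_lines.append(json.dumps(
                {"stage": stage, "delta_ci": round(change.delta_ci, 6),
                 "pct_explained": round(change.percent_explained, 2)}))
        else:
            log_lines.append(json.dumps(
                {"stage": "oaxaca", "skipped": "single wave configured"}))

        stage = "meta"
        meta = {"version": __version__, "options": config.options,
                "waves": config.waves, "ame": ame, "weighted": weighted}
        (out / "meta.json").write_text(json.dumps(meta, indent=1, default=str))
        (out / "logs" / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return {"datasets": datasets, "results": results, "oaxaca": change,
            "ci_table": ci_table}


def _curves_figure(datasets, png_path, csv_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    records = []
    for ds in datasets:
        curve = concentration_curve(ds.rank_score, ds.outcome, ds.weight,
                                    label=ds.label)
        ax.plot(curve.population_share, curve.outcome_share, label=ds.label)
        records.append(pd.DataFrame({
            "label": ds.label,
            "population_share": curve.population_share,
            "outcome_share": curve.outcome_share,
        }))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="equality")
    ax.set_xlabel("cumulative population share (poorest first)")
    ax.set_ylabel("cumulative outcome share")
    ax.legend()
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    pd.concat(records, ignore_index=True).to_csv(csv_path, index=False)
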