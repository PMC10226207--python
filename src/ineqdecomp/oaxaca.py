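"""Oaxaca-Blinder decomposition of the change in a concentration index.

Given per-covariate elasticities ζ_k and covariate concentration indices
C_k for two survey waves (t−1 and t), the change ΔC = C_t − C_{t−1}
splits covariate by covariate into a part due to changing covariate
inequality and a part due to changing elasticities, under two symmetric
weightings:

    variant 1:  ζ_{k,t}   (C_{k,t} − C_{k,t−1})  +  C_{k,t−1} (ζ_{k,t} − ζ_{k,t−1})
    variant 2:  ζ_{k,t−1} (C_{k,t} − C_{k,t−1})  +  C_{k,t}   (ζ_{k,t} − ζ_{k,t−1})

Both variants sum to the same per-covariate total
ζ_{k,t} C_{k,t} − ζ_{k,t−1} C_{k,t−1} (an algebraic identity); the
unexplained change is the remainder ΔC − Σ_k totals.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import DataError
from .wagstaff import DecompositionTable

__all__ = ["OaxacaRow", "OaxacaTable", "oaxaca", "contribution_chart"]


@dataclass
class OaxacaRow:
    """Two-variant split of one covariate's contribution to ΔC."""

    label: str
    group: str
    v1_dC: float
    v1_dZ: float
    v2_dC: float
    v2_dZ: float
    total: float
    percent: float


@dataclass
class OaxacaTable:
    """Change decomposition between two waves.

    ``explained + residual_change == delta_ci`` exactly; per-row,
    ``v1_dC + v1_dZ == v2_dC + v2_dZ == total`` up to rounding noise of
    order machine epsilon.
    """

    rows: list[OaxacaRow]
    delta_ci: float
    explained: float
    residual_change: float
    percent_explained: float
    percent_residual: float
    label_t: str = ""
    label_t1: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"covariate": r.label, "group": r.group, "v1_dC": r.v1_dC,
              "v1_dZ": r.v1_dZ, "v2_dC": r.v2_dC, "v2_dZ": r.v2_dZ,
              "total": r.total, "percent": r.percent} for r in self.rows])

    def grouped_percents(self) -> pd.Series:
        """Per-covariate-group percent totals (education levels pooled etc.),
        with the residual appended; sums to 100."""
        frame = self.to_frame()
        by_group = frame.groupby("group", sort=False)["percent"].sum()
        by_group["residual"] = self.percent_residual
        return by_group

    def to_json(self, path=None) -> str:
        payload = {
            "label_t": self.label_t, "label_t1": self.label_t1,
            "delta_ci": self.delta_ci, "explained": self.explained,
            "residual_change": self.residual_change,
            "percent_explained": self.percent_explained,
            "percent_residual": self.percent_residual,
            "rows": [r.__dict__ for r in self.rows],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def oaxaca(dec_t: DecompositionTable, dec_t1: DecompositionTable) -> OaxacaTable:
    """Decompose ΔC between a later wave ``dec_t`` and an earlier ``dec_t1``.

    Both tables must cover exactly the same covariate labels (rows are
    aligned by label; a label present in only one wave is an error — no
    silent zero-filling).
    """
    labels_t = [r.label for r in dec_t.rows]
    labels_t1 = [r.label for r in dec_t1.rows]
    if set(labels_t) != set(labels_t1):
        only_t = sorted(set(labels_t) - set(labels_t1))
        only_t1 = sorted(set(labels_t1) - set(labels_t))
        raise DataError(
            "covariate sets differ between waves: "
            f"only in later wave {only_t}, only in earlier wave {only_t1}")
    by_label_t1 = {r.label: r for r in dec_t1.rows}

    delta_ci = dec_t.total_ci - dec_t1.total_ci
    rows: list[OaxacaRow] = []
    for rt in dec_t.rows:
        r1 = by_label_t1[rt.label]
        z_t, z_1 = rt.elasticity, r1.elasticity
        c_t, c_1 = rt.ci_k, r1.ci_k
        total = z_t * c_t - z_1 * c_1
        rows.append(OaxacaRow(
            label=rt.label, group=rt.group,
            v1_dC=z_t * (c_t - c_1), v1_dZ=c_1 * (z_t - z_1),
            v2_dC=z_1 * (c_t - c_1), v2_dZ=c_t * (z_t - z_1),
            total=total,
            percent=100.0 * total / delta_ci if delta_ci != 0 else np.nan))
    explained = float(np.sum([r.total for r in rows]))
    residual_change = delta_ci - explained
    if delta_ci != 0:
        pct_explained = 100.0 * explained / delta_ci
        pct_residual = 100.0 * residual_change / delta_ci
    else:
        pct_explained = pct_residual = np.nan
    return OaxacaTable(rows=rows, delta_ci=delta_ci, explained=explained,
                       residual_change=residual_change,
                       percent_explained=pct_explained,
                       percent_residual=pct_residual,
                       label_t=dec_t.label, label_t1=dec_t1.label)


def contribution_chart(table: OaxacaTable, out, csv_out=None, title=None):
    """Horizontal bar chart of grouped percent contributions to ΔC.

    Covariate levels are pooled to their parent covariate (all education
    dummies in one bar, etc.) and the residual is shown as its own bar.
    A CSV of the plotted values is written alongside (``csv_out``, or the
    image path with a ``.csv`` suffix).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grouped = table.grouped_percents()
    csv_path = csv_out if csv_out is not None else str(out).rsplit(".", 1)[0] + ".csv"
    grouped.rename("percent_of_delta_ci").to_csv(csv_path, header=True)

    fig, ax = plt.subplots(figsize=(7, 0.4 * len(grouped) + 1.5))
    colors = ["#b2182b" if v >= 0 else "#2166ac" for v in grouped.to_numpy()]
    ax.barh(grouped.index.astype(str), grouped.to_numpy(), color=colors)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("contribution to change in concentration index (%)")
    ax.set_title(title or f"Change decomposition: "
                 f"{table.label_t1 or 't-1'} → {table.label_t or 't'}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return grouped
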