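"""Published worked-example tables shipped with the package.

The decomposition tables of a national maternal-and-child-health equity
analysis (Nepal DHS 2011/2016) print, for every covariate, both the
elasticity ζ_k and the covariate concentration index C_k — which makes
the contribution arithmetic (ζ_k × C_k) and the full between-wave change
decomposition self-contained and recomputable without the restricted
microdata.  These tables are shipped as plain CSV and used as worked
examples and regression anchors:

* ``anc`` — decomposition of the concentration index of "fewer than four
  antenatal-care visits", both waves;
* ``pnc`` — same for "no postnatal checkup within two months";
* the matching published change-decomposition cells for the ANC outcome.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .wagstaff import DecompositionTable

__all__ = [
    "REFERENCE_TOTALS",
    "load_reference_inputs",
    "reference_decomposition",
    "load_reference_change_cells",
]

#: Published totals (CI, explained, residual) per outcome and wave.
REFERENCE_TOTALS = {
    "anc": {
        "2011": {"ci": -0.2184, "explained": -0.2199, "residual": 0.0015},
        "2016": {"ci": -0.1897, "explained": -0.1956, "residual": 0.0059},
    },
    "pnc": {
        "2011": {"ci": -0.1643, "explained": -0.1624, "residual": -0.0019},
        "2016": {"ci": -0.0504, "explained": -0.0470, "residual": -0.0034},
    },
}

_FILES = {
    "anc": "anc_decomposition_2011_2016.csv",
    "pnc": "pnc_decomposition_2011_2016.csv",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ineqdecomp.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_reference_inputs(outcome: str = "anc") -> pd.DataFrame:
    """Per-covariate published inputs: ζ_k, C_k and the printed
    contribution for both waves, one row per regressor."""
    if outcome not in _FILES:
        raise KeyError(f"unknown reference outcome {outcome!r}; "
                       f"choose from {sorted(_FILES)}")
    return _read(_FILES[outcome])


def reference_decomposition(outcome: str, wave: str) -> DecompositionTable:
    """Reconstruct a :class:`DecompositionTable` from the published ζ_k /
    C_k pairs of one wave (contributions recomputed, not copied)."""
    df = load_reference_inputs(outcome)
    totals = REFERENCE_TOTALS[outcome][wave]
    return DecompositionTable.from_components(
        labels=df["label"].tolist(),
        elasticities=df[f"zeta_{wave}"].to_numpy(),
        ci_ks=df[f"ci_{wave}"].to_numpy(),
        total_ci=totals["ci"],
        label=f"{outcome}-{wave}",
        groups=dict(zip(df["label"], df["group"])),
    )


def load_reference_change_cells() -> pd.DataFrame:
    """Published change-decomposition cells for the ANC outcome (both
    variant splits, totals and percent shares)."""
    return _read("anc_change_decomposition_2011_2016.csv")
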