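"""Relative sensitivity coefficients by finite-difference perturbation.

For an output y depending on an input parameter x, the dimensionless
relative sensitivity coefficient is

    c* = (x / y) * (dy / dx),

so for a pure power law y = x^m, c* = m exactly.  The derivative is
approximated by perturbing the parameter multiplicatively by 1% (forward
difference by default; central optional at twice the cost) and re-running
the whole pipeline.  Fields are perturbed globally by the same factor,
treating each parameter as a single scalar knob.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

FLOW_PARAMS = ("alpha", "mu", "phi_a", "phi_v", "k_a", "k_v", "gamma_a", "gamma_v")
FLOW_OUTPUTS = ("p_a", "p_v", "P")
KINETIC_OUTPUTS = ("TTP", "MTT")


def relative_sensitivity(runner: Callable[[dict[str, float]], dict[str, np.ndarray]],
                         parameter: str, rel: float = 0.01,
                         scheme: str = "forward",
                         baseline: dict[str, np.ndarray] | None = None
                         ) -> dict[str, np.ndarray]:
    """c* fields of every output of ``runner`` w.r.t. one parameter.

    ``runner`` maps a dict of multiplicative factors to a dict of output
    arrays.  Entries where the baseline output is (near) zero are undefined
    and flagged as nan.
    """
    if scheme not in ("forward", "central"):
        raise ValueError("scheme must be 'forward' or 'central'")
    y0 = runner({}) if baseline is None else baseline
    y_hi = runner({parameter: 1.0 + rel})
    out = {}
    for name, base in y0.items():
        base = np.asarray(base, dtype=float)
        if scheme == "forward":
            dy = np.asarray(y_hi[name], dtype=float) - base
            denom = rel
        else:
            y_lo = runner({parameter: 1.0 - rel})
            dy = np.asarray(y_hi[name], dtype=float) - np.asarray(y_lo[name], float)
            denom = 2.0 * rel
        with np.errstate(divide="ignore", invalid="ignore"):
            c = dy / (denom * base)
        scale = np.nanmax(np.abs(base)) if base.size else 0.0
        undef = ~np.isfinite(base) | (np.abs(base) <= 1e-12 * max(scale, 1.0))
        c = np.where(undef, np.nan, c)
        out[name] = c
    return out


def sensitivity_table(runner, parameters: Iterable[str] = FLOW_PARAMS,
                      rel: float = 0.01, scheme: str = "forward") -> pd.DataFrame:
    """Spatially averaged c* for every (parameter, output) pair.

    Rows are input parameters, columns output quantities — the compact
    summary of how 1% input uncertainty propagates through the model.
    """
    baseline = runner({})
    rows = {}
    for p in parameters:
        fields = relative_sensitivity(runner, p, rel=rel, scheme=scheme,
                                      baseline=baseline)
        rows[p] = {name: float(np.nanmean(c)) for name, c in fields.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
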