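"""Log transformation, SLG sums and the ERMI value.

The Environmental Relative Moldiness Index for a home is

    ERMI = SLG1 - SLG2

where SLG1 is the sum of log10 dust concentrations over the 26 Group 1
(water-damage-indicator) species and SLG2 the same sum over the 10 Group 2
(outdoor-background) species.  The scale is unitless, runs from about -10
to 20 on the national reference sample, and is read in quartiles.

Non-detect convention: a concentration below the log floor (default 1
cell/mg, so any non-detect stored as 0) contributes a log value of 0.  This
keeps SLG sums nonnegative and matches the index's national scale; the
floor is configurable via ``log_floor``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError, InsufficientDataError
from .panel import SpeciesPanel

__all__ = ["log_transform", "compute_ermi", "ermi_quartiles"]


def log_transform(conc, log_floor: float = 1.0) -> pd.DataFrame:
    """log10-transform a homes-by-species concentration table.

    Values >= ``log_floor`` map to log10(value); values below (including
    non-detect 0) map to 0.0.  Output is therefore nonnegative and finite
    for the default floor of 1.
    """
    from .synth import HomeMatrix

    if isinstance(conc, HomeMatrix):
        conc = conc.conc
    df = pd.DataFrame(conc).astype(float)
    vals = df.to_numpy()
    if (vals < 0).any():
        raise InputError("concentrations must be nonnegative")
    out = np.zeros_like(vals)
    mask = vals >= log_floor
    out[mask] = np.log10(vals[mask])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def compute_ermi(logm: pd.DataFrame, panel: SpeciesPanel) -> pd.DataFrame:
    """Per-home SLG1, SLG2 and ERMI from a log-transformed matrix.

    Columns must cover the full panel (canonical names or aliases).
    Returns a DataFrame with columns ``slg1, slg2, ermi``.
    """
    logm = pd.DataFrame(logm)
    canonical = {}
    for col in logm.columns:
        rec = panel.resolve(col)  # raises on unknown label
        if rec.name in canonical:
            raise AlignmentError(f"duplicate column for species {rec.name!r}")
        canonical[rec.name] = col
    missing = [n for n in panel.names if n not in canonical]
    if missing:
        raise AlignmentError(f"missing species columns: {missing}")
    g1 = [canonical[n] for n in panel.group_names(1)]
    g2 = [canonical[n] for n in panel.group_names(2)]
    slg1 = logm[g1].sum(axis=1)
    slg2 = logm[g2].sum(axis=1)
    return pd.DataFrame({"slg1": slg1, "slg2": slg2, "ermi": slg1 - slg2})


def ermi_quartiles(values) -> np.ndarray:
    """Empirical quartile class (1-4) of each value among the supplied values.

    Cut points are the 25/50/75 percentiles (linear interpolation between
    order statistics); a value equal to a cut point falls in the lower
    quartile.  Degenerate all-equal input puts every home in quartile 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise InputError("values must be one-dimensional")
    if len(values) < 4:
        raise InsufficientDataError("quartiles need at least 4 values")
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    out = np.full(len(values), 4, dtype=int)
    out[values <= q75] = 3
    out[values <= q50] = 2
    out[values <= q25] = 1
    return out
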