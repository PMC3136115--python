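"""Geographic gradient regressions.

Each species' log10 concentration (and each untransformed index SLG1, SLG2,
ERMI) is regressed on longitude and latitude by Gaussian maximum likelihood
— ordinary least squares with the n-denominator variance estimate — with an
intercept.  Wald statistics Z = beta/SE are referred to the standard normal,
giving two-sided p-values; at survey scale (n ≈ 1083) this is
indistinguishable from the t reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ConfigError, InsufficientDataError
from .panel import SpeciesPanel

__all__ = ["GeoRegressionFit", "fit_geo", "fit_all", "significance_counts"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class GeoRegressionFit:
    """ML fit of response ~ 1 + longitude + latitude.

    ``z_* = beta_*/se_*`` and ``p_* = 2*(1 - Phi(|z_*|))``; a residual
    variance of (numerically) zero marks the fit ``degenerate`` with
    infinite Z and zero p.
    """

    response: str
    beta0: float
    beta_lon: float
    beta_lat: float
    se_lon: float
    se_lat: float
    z_lon: float
    z_lat: float
    p_lon: float
    p_lat: float
    sigma2: float
    n: int
    degenerate: bool = False


def fit_geo(y, lon, lat, response: str = "y") -> GeoRegressionFit:
    """Fit one geographic regression by Gaussian maximum likelihood.

    Requires at least 4 homes and a non-collinear (intercept, lon, lat)
    design.  Exactly linear responses (zero residual variance) return a
    degenerate fit whose coefficients are still exact.
    """
    y = np.asarray(y, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(y)
    if n < 4:
        raise InsufficientDataError("geographic regression needs >= 4 homes")
    if not (len(lon) == len(lat) == n):
        raise ConfigError("y, lon, lat must have equal length")
    X = np.column_stack([np.ones(n), lon, lat])
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearityError("longitude/latitude design is singular")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n  # ML (n-denominator) variance
    xtx_inv = np.linalg.inv(X.T @ X)
    scale = max(sigma2, 0.0)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * scale, 0.0))
    degenerate = sigma2 <= _DEGENERATE_TOL * max(1.0, float(y @ y) / n)
    if degenerate:
        warnings.warn(
            f"degenerate fit for {response!r}: residual variance ~ 0, Z infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        z = np.where(np.abs(beta[1:]) > 0, np.inf * np.sign(beta[1:]), 0.0)
    else:
        z = beta[1:] / se[1:]
    p = 2.0 * stats.norm.sf(np.abs(z))
    return GeoRegressionFit(
        response=response,
        beta0=float(beta[0]),
        beta_lon=float(beta[1]),
        beta_lat=float(beta[2]),
        se_lon=float(se[1]),
        se_lat=float(se[2]),
        z_lon=float(z[0]),
        z_lat=float(z[1]),
        p_lon=float(p[0]),
        p_lat=float(p[1]),
        sigma2=sigma2,
        n=n,
        degenerate=degenerate,
    )


def fit_all(home_matrix, panel: SpeciesPanel, log_floor: float = 1.0) -> pd.DataFrame:
    """Run the full published regression battery on a homes matrix.

    One row per species (response = log10 concentration) plus SLG1, SLG2 and
    ERMI (untransformed).  Returns a table shaped like the published one:
    ``response, beta_lon, beta_lat, z_lon, p_lon, z_lat, p_lat``.
    """
    from .ermi import compute_ermi, log_transform

    logm = log_transform(home_matrix.conc, log_floor=log_floor)
    indices = compute_ermi(logm, panel)
    lon, lat = home_matrix.longitude, home_matrix.latitude
    rows = []
    responses = [(name, logm[name]) for name in panel.names]
    responses += [
        ("SLG1", indices["slg1"]),
        ("SLG2", indices["slg2"]),
        ("ERMI", indices["ermi"]),
    ]
    for name, y in responses:
        fit = fit_geo(y, lon, lat, response=name)
        rows.append(
            {
                "response": name,
                "beta_lon": fit.beta_lon,
                "beta_lat": fit.beta_lat,
                "z_lon": fit.z_lon,
                "p_lon": fit.p_lon,
                "z_lat": fit.z_lat,
                "p_lat": fit.p_lat,
            }
        )
    return pd.DataFrame(rows)


def significance_counts(
    fits: pd.DataFrame, panel: SpeciesPanel, alpha: float = 0.05
) -> tuple[int, int]:
    """Count species per ERMI group significant on either coordinate.

    A species counts if ``p_lon < alpha`` or ``p_lat < alpha``.  ``fits``
    must provide one row per panel species (index rows are ignored);
    returns ``(n_group1, n_group2)``.
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    sub = fits.set_index("response")
    counts = {1: 0, 2: 0}
    for name in panel.names:
        if name not in sub.index:
            raise ConfigError(f"missing regression fit for species {name!r}")
        row = sub.loc[name]
        if row["p_lon"] < alpha or row["p_lat"] < alpha:
            counts[panel.resolve(name).group] += 1
    return counts[1], counts[2]
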