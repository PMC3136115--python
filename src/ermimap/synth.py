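"""Synthetic survey-like home/mold datasets.

The national survey data behind the ERMI mold-geography analysis are not
public, so this module generates datasets with the same statistical anatomy:

* ~1083 homes scattered around ~82 metropolitan sampling locales inside the
  continental-US bounding box;
* per-species log10-normal dust concentrations (cell equivalents per mg);
* weak linear longitude/latitude gradients for the subset of species whose
  published regressions were significant, with the published signs;
* a 7-block latent-factor correlation structure among the 36 species that
  mirrors the published variable-cluster memberships and R-squared
  magnitudes (factor = published cluster, loading = sqrt of the published
  own-cluster R-squared);
* left-censoring at a detection limit, with non-detects stored as 0.

The generating model for home ``h`` and species ``s`` is, on the log10 scale,

    x[h, s] = mu_s + gamma_lon_s * lon_h + gamma_lat_s * lat_h
              + loading_s * F[factor_s, h] + community offset + e[h, s]

with ``F`` i.i.d. standard-normal latent factors per (factor, home) and
``e ~ N(0, sigma_resid_s)``.  Concentrations are ``10**x``, then values
below the detection limit are set to 0 (non-detect).  Latent factors and
residuals are always drawn independently of home location; *spatial*
community structure (coherent home subsets) exists only when
``n_communities > 0``, in which case whole locales are assigned to
communities that share per-species mean offsets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .panel import SpeciesPanel, load_panel, load_table1, load_table2

__all__ = [
    "LAT_BOUNDS",
    "LON_BOUNDS",
    "SynthConfig",
    "HomeMatrix",
    "default_gradients",
    "default_loadings",
    "generate",
    "spatially_unstructured",
]

#: Continental-US coordinate box (decimal degrees).
LAT_BOUNDS = (24.0, 50.0)
LON_BOUNDS = (-125.0, -66.0)

#: Slope applied per unit of published Z to build default gradients
#: (log10 concentration units per degree).
GRADIENT_PER_Z = 0.002


def default_gradients(panel: SpeciesPanel | None = None, alpha: float = 0.05):
    """Per-species default (gamma_lon, gamma_lat) built from the published
    regression table: species significant at ``alpha`` get a weak slope with
    the published sign (``GRADIENT_PER_Z`` log10 units/degree per unit Z),
    everything else gets 0."""
    panel = panel or load_panel()
    t1 = load_table1(panel).set_index("response")
    g_lon = np.zeros(len(panel))
    g_lat = np.zeros(len(panel))
    for i, name in enumerate(panel.names):
        row = t1.loc[name]
        if row["p_lon"] < alpha:
            g_lon[i] = GRADIENT_PER_Z * row["z_lon"]
        if row["p_lat"] < alpha:
            g_lat[i] = GRADIENT_PER_Z * row["z_lat"]
    return g_lon, g_lat


def default_loadings(panel: SpeciesPanel | None = None):
    """Per-species default (factor_id, loading) from the published cluster
    table: factor = cluster id, loading = sqrt(own-cluster R-squared)."""
    panel = panel or load_panel()
    t2 = load_table2(panel).set_index("species")
    factor = np.empty(len(panel), dtype=int)
    loading = np.empty(len(panel))
    for i, name in enumerate(panel.names):
        row = t2.loc[name]
        factor[i] = int(row["cluster"])
        loading[i] = float(np.sqrt(row["r2_own"]))
    return factor, loading


@dataclass
class SynthConfig:
    """Generator settings.

    Array-valued fields accept a scalar (broadcast over the 36 species) or a
    length-36 array in panel order; ``None`` selects the published-table
    defaults described in the module docstring.
    """

    n_homes: int = 1083
    n_locales: int = 82
    locale_spread: float = 0.3          # sd (degrees) of homes around locale
    mu: float | np.ndarray = 1.5        # mean log10 concentration
    sigma_resid: float | np.ndarray = 0.8
    gamma_lon: float | np.ndarray | None = None
    gamma_lat: float | np.ndarray | None = None
    factor_ids: np.ndarray | None = None
    loadings: float | np.ndarray | None = None
    detection_limit: float = 1.0        # cells/mg; concentrations below -> 0
    n_communities: int = 0              # 0 = no home-subset community structure
    community_sd: float = 0.0           # sd of per-community species offsets
    seed: int = 0

    def validate(self, n_species: int) -> None:
        if self.n_homes < 1 or self.n_locales < 1:
            raise ConfigError("n_homes and n_locales must be positive")
        if self.n_locales > self.n_homes:
            raise ConfigError("n_locales must not exceed n_homes")
        if self.locale_spread < 0:
            raise ConfigError("locale_spread must be nonnegative")
        if np.any(np.asarray(self.sigma_resid, dtype=float) <= 0):
            raise ConfigError("sigma_resid must be positive")
        if self.detection_limit < 0:
            raise ConfigError("detection_limit must be nonnegative")
        if self.loadings is not None:
            lo = np.asarray(self.loadings, dtype=float)
            if np.any((lo < 0) | (lo > 1)):
                raise ConfigError("loadings must lie in [0, 1]")
        if self.n_communities < 0 or self.community_sd < 0:
            raise ConfigError("community settings must be nonnegative")


@dataclass
class HomeMatrix:
    """Homes-by-species concentration matrix with per-home coordinates.

    ``conc`` holds nonnegative concentrations (cell equivalents per mg of
    sieved dust) with one column per panel species; non-detect is stored
    as 0.  ``locale_truth`` carries the generating locale id and is only
    present for synthetic data.
    """

    home_ids: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    conc: pd.DataFrame
    locale_truth: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        n = len(self.home_ids)
        if not (len(self.latitude) == len(self.longitude) == len(self.conc) == n):
            raise InputError("home_ids, coordinates and conc must agree in length")
        if (self.conc.to_numpy() < 0).any():
            raise InputError("concentrations must be nonnegative")

    @property
    def n_homes(self) -> int:
        return len(self.home_ids)

    @property
    def species(self) -> list[str]:
        return list(self.conc.columns)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "home_id": self.home_ids,
                "latitude": self.latitude,
                "longitude": self.longitude,
            }
        )
        if self.locale_truth is not None:
            out["locale_truth"] = self.locale_truth
        return pd.concat([out, self.conc.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        """Write the homes table; the generator seed is recorded in a
        leading ``#`` comment so every artifact is self-describing."""
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# ermimap homes table; seed={self.seed}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "HomeMatrix":
        text = Path(path).read_text()
        seed = None
        lines = text.splitlines(keepends=True)
        body = []
        for ln in lines:
            if ln.startswith("#"):
                if "seed=" in ln:
                    seed = int(ln.split("seed=")[1].strip())
                continue
            body.append(ln)
        df = pd.read_csv(io.StringIO("".join(body)))
        meta_cols = ["home_id", "latitude", "longitude"]
        locale = None
        if "locale_truth" in df.columns:
            locale = df["locale_truth"].to_numpy()
            meta_cols.append("locale_truth")
        conc = df.drop(columns=meta_cols)
        return cls(
            home_ids=df["home_id"].astype(str).tolist(),
            latitude=df["latitude"].to_numpy(float),
            longitude=df["longitude"].to_numpy(float),
            conc=conc,
            locale_truth=locale,
            seed=seed,
        )


def _per_species(value, p: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(p, float(arr))
    if arr.shape != (p,):
        raise ConfigError(f"{name} must be scalar or length-{p}, got {arr.shape}")
    return arr.copy()


def generate(config: SynthConfig, panel: SpeciesPanel | None = None) -> HomeMatrix:
    """Draw a synthetic homes-by-species dataset under ``config``.

    Deterministic: the same config (including seed) yields a bit-identical
    matrix.
    """
    panel = panel or load_panel()
    p = len(panel)
    config.validate(p)
    rng = np.random.default_rng(config.seed)

    mu = _per_species(config.mu, p, "mu")
    sigma = _per_species(config.sigma_resid, p, "sigma_resid")
    if config.gamma_lon is None or config.gamma_lat is None:
        d_lon, d_lat = default_gradients(panel)
        g_lon = d_lon if config.gamma_lon is None else _per_species(config.gamma_lon, p, "gamma_lon")
        g_lat = d_lat if config.gamma_lat is None else _per_species(config.gamma_lat, p, "gamma_lat")
    else:
        g_lon = _per_species(config.gamma_lon, p, "gamma_lon")
        g_lat = _per_species(config.gamma_lat, p, "gamma_lat")
    if config.factor_ids is None or config.loadings is None:
        d_fac, d_load = default_loadings(panel)
        factor = d_fac if config.factor_ids is None else np.asarray(config.factor_ids, int)
        loading = d_load if config.loadings is None else _per_species(config.loadings, p, "loadings")
    else:
        factor = np.asarray(config.factor_ids, dtype=int)
        loading = _per_species(config.loadings, p, "loadings")
    if factor.shape != (p,):
        raise ConfigError(f"factor_ids must be length-{p}")

    n, k = config.n_homes, config.n_locales
    centroids_lat = rng.uniform(*LAT_BOUNDS, size=k)
    centroids_lon = rng.uniform(*LON_BOUNDS, size=k)
    locale = rng.integers(0, k, size=n)
    # guarantee every locale non-empty
    locale[:k] = np.arange(k)
    rng.shuffle(locale)
    lat = np.clip(
        centroids_lat[locale] + rng.normal(0, config.locale_spread, n), *LAT_BOUNDS
    )
    lon = np.clip(
        centroids_lon[locale] + rng.normal(0, config.locale_spread, n), *LON_BOUNDS
    )

    factor_labels = np.unique(factor)
    F = rng.standard_normal((len(factor_labels), n))
    fac_idx = np.searchsorted(factor_labels, factor)

    x = (
        mu[None, :]
        + lon[:, None] * g_lon[None, :]
        + lat[:, None] * g_lat[None, :]
        + (loading[None, :] * F[fac_idx, :].T)
    )

    if config.n_communities > 0 and config.community_sd > 0:
        locale_comm = rng.integers(0, config.n_communities, size=k)
        offsets = rng.normal(0, config.community_sd, (config.n_communities, p))
        x = x + offsets[locale_comm[locale], :]

    x = x + rng.standard_normal((n, p)) * sigma[None, :]

    conc = np.power(10.0, x)
    conc[conc < config.detection_limit] = 0.0

    width = len(str(n))
    ids = [f"H{i:0{width}d}" for i in range(1, n + 1)]
    return HomeMatrix(
        home_ids=ids,
        latitude=lat,
        longitude=lon,
        conc=pd.DataFrame(conc, columns=panel.names),
        locale_truth=locale,
        seed=config.seed,
    )


def spatially_unstructured(
    config: SynthConfig, panel: SpeciesPanel | None = None
) -> HomeMatrix:
    """Generate data with *no* home-subset community structure: latent
    factors and residuals independent of locale membership and coordinates.
    Gradients are allowed; this is the null the partition-validity analysis
    should fail to reject."""
    return generate(replace(config, n_communities=0, community_sd=0.0), panel)
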