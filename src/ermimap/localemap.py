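"""Locale aggregation, natural-breaks classification and layer export.

Surveyed homes cluster geographically around metropolitan "sampling
locales" (the survey's primary sampling units).  For mapping, homes are
collapsed to locales by k-means on (latitude, longitude), per-locale means
of the FPC scores and ERMI-related indices are computed, and each mapped
variable is classified into five natural-break (Fisher-Jenks) categories.
Class 1 is drawn smallest/lightest, class 5 largest/darkest; the exported
layer carries integer grey/size ranks rather than renderer-specific
symbols.

The Jenks optimization here is exact: a dynamic program over sorted values
minimizing total within-class sum of squared deviations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .validity import kmeans

__all__ = [
    "assign_locales",
    "aggregate",
    "jenks_breaks",
    "classify",
    "BreaksClassification",
    "export_layer",
    "read_layer",
]


def assign_locales(lat, lon, n_locales: int = 82, seed: int = 0) -> np.ndarray:
    """Collapse home coordinates to ``n_locales`` plotting positions.

    Seeded k-means on (lat, lon); returns 0-based locale labels, all
    locales non-empty.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) != len(lon):
        raise ConfigError("lat and lon must have equal length")
    if not 1 <= n_locales <= len(lat):
        raise ConfigError("n_locales must be in [1, n_homes]")
    if n_locales == 1:
        return np.zeros(len(lat), dtype=int)
    return kmeans(np.column_stack([lat, lon]), n_locales, seed=seed)


def aggregate(values: pd.DataFrame, labels, n_locales: int | None = None) -> pd.DataFrame:
    """Per-locale arithmetic means.

    ``values`` must contain ``latitude`` and ``longitude`` columns; every
    other numeric column is averaged as well.  Returns one row per locale
    with ``locale_id``, ``n_homes``, ``mean_lat``, ``mean_lon`` and the
    mean of each remaining column.  If ``n_locales`` is given, every locale
    id in ``range(n_locales)`` must be non-empty.
    """
    values = pd.DataFrame(values)
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise InputError("labels must cover all homes")
    for col in ("latitude", "longitude"):
        if col not in values.columns:
            raise InputError(f"values must contain a {col!r} column")
    if n_locales is not None:
        present = set(np.unique(labels))
        missing = sorted(set(range(n_locales)) - present)
        if missing:
            raise InputError(f"empty locales: {missing}")
    grouped = values.groupby(labels)
    out = grouped.mean(numeric_only=True)
    out = out.rename(columns={"latitude": "mean_lat", "longitude": "mean_lon"})
    out.insert(0, "n_homes", grouped.size())
    out.index.name = "locale_id"
    return out.reset_index()


@dataclass(frozen=True)
class BreaksClassification:
    """Natural-breaks classification of one mapped variable.

    ``breaks`` are the interior class upper bounds (ascending, length
    ``n_classes - 1``); class i covers ``(breaks[i-2], breaks[i-1]]`` with
    the first class open below and the last open above.  ``classes`` are
    1-based per locale; the grey-scale and symbol-size ranks equal the
    class (1 = lightest/smallest).
    """

    variable: str
    breaks: tuple[float, ...]
    classes: np.ndarray
    n_classes: int

    @property
    def grey_ranks(self) -> np.ndarray:
        return self.classes

    @property
    def size_ranks(self) -> np.ndarray:
        return self.classes


def _jenks_boundaries(sorted_vals: np.ndarray, k: int) -> list[int]:
    """Exact Fisher-Jenks DP: indices of the last element of classes 1..k-1."""
    n = len(sorted_vals)
    csum = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    csum2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def ssd(i, j):  # inclusive slice i..j
        m = j - i + 1
        s = csum[j + 1] - csum[i]
        return (csum2[j + 1] - csum2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n), INF)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        cost[1, j] = ssd(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, n):
            best, arg = INF, c - 2
            for i in range(c - 2, j):
                val = cost[c - 1, i] + ssd(i + 1, j)
                if val < best - 1e-12:
                    best, arg = val, i
            cost[c, j] = best
            back[c, j] = arg
    bounds = []
    j = n - 1
    for c in range(k, 1, -1):
        j = back[c, j]
        bounds.append(j)
    return bounds[::-1]


def jenks_breaks(values, n_classes: int = 5, variable: str = "value") -> BreaksClassification:
    """Classify values into ``n_classes`` natural-break categories.

    Exact optimization: boundaries minimize the total within-class sum of
    squared deviations over all placements.  With fewer distinct values
    than classes, the class count degrades to the number of distinct values
    (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise InputError("values must be a non-empty 1-D array")
    if n_classes < 1:
        raise ConfigError("n_classes must be >= 1")
    distinct = np.unique(values)
    k = min(n_classes, len(distinct))
    if k < n_classes:
        warnings.warn(
            f"only {len(distinct)} distinct values; using {k} classes",
            RuntimeWarning,
            stacklevel=2,
        )
    if k == 1:
        return BreaksClassification(variable, (), np.ones(len(values), int), 1)
    sorted_vals = np.sort(values)
    # DP runs on the full sorted sample; ties stay together because breaks
    # are value thresholds, so equal values always land in the same class
    bidx = _jenks_boundaries(sorted_vals, k)
    breaks = tuple(float(sorted_vals[i]) for i in bidx)
    classes = classify(values, breaks)
    return BreaksClassification(variable, breaks, classes, k)


def classify(values, breaks) -> np.ndarray:
    """1-based class of each value given ascending interior break upper
    bounds; values equal to a break fall in the lower class."""
    values = np.asarray(values, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    return (np.searchsorted(breaks, values, side="left") + 1).astype(int)


def export_layer(
    summaries: pd.DataFrame,
    classification: BreaksClassification,
    path,
    format: str = "geojson",
) -> None:
    """Write a classified locale point layer.

    ``geojson``: RFC 7946 FeatureCollection of Points (coordinates
    [lon, lat]) with properties locale_id, n_homes, value, class,
    grey_rank, size_rank.  ``csv``: the same columns flat.  The value
    plotted is ``summaries[classification.variable]``.
    """
    summaries = pd.DataFrame(summaries)
    if len(summaries) == 0:
        raise InputError("no locales to export")
    var = classification.variable
    if var not in summaries.columns:
        raise InputError(f"summaries lack variable column {var!r}")
    if len(classification.classes) != len(summaries):
        raise InputError("classification does not cover the locales")
    if format not in ("geojson", "csv"):
        raise ConfigError(f"unknown format {format!r}")
    records = []
    for i, row in enumerate(summaries.itertuples(index=False)):
        rowd = row._asdict()
        records.append(
            {
                "locale_id": int(rowd["locale_id"]),
                "n_homes": int(rowd["n_homes"]),
                "mean_lat": float(rowd["mean_lat"]),
                "mean_lon": float(rowd["mean_lon"]),
                "value": float(rowd[var]),
                "class": int(classification.classes[i]),
                "grey_rank": int(classification.classes[i]),
                "size_rank": int(classification.classes[i]),
            }
        )
    if format == "csv":
        pd.DataFrame(records).to_csv(path, index=False)
        return
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [rec["mean_lon"], rec["mean_lat"]],
            },
            "properties": {k: v for k, v in rec.items()
                           if k not in ("mean_lat", "mean_lon")},
        }
        for rec in records
    ]
    layer = {
        "type": "FeatureCollection",
        "features": features,
        "variable": var,
        "breaks": list(classification.breaks),
    }
    with open(path, "w") as fh:
        json.dump(layer, fh, indent=1)


def read_layer(path) -> pd.DataFrame:
    """Read back an exported layer (either format) as a flat DataFrame."""
    path = str(path)
    if path.endswith(".csv"):
        return pd.read_csv(path)
    with open(path) as fh:
        layer = json.load(fh)
    rows = []
    for feat in layer["features"]:
        lon, lat = feat["geometry"]["coordinates"]
        rows.append({**feat["properties"], "mean_lat": lat, "mean_lon": lon})
    return pd.DataFrame(rows)
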