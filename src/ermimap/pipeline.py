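"""End-to-end orchestration: simulate → index → regress → scan → cluster → map.

Stage order follows the analysis it reproduces: per-home indices and
geographic regressions and the partition-validity scan run on the full home
set first; variable clustering reduces the 36 species to FPC clusters; the
locale stage then collapses homes to sampling locales and classifies each
mapped variable (one layer per FPC cluster plus SLG1, SLG2 and ERMI) into
five natural-break categories.

All randomness flows from a single root seed through named per-stage
substreams, so a (config, seed) pair maps to one manifest of checksummed
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ermi as ermi_mod
from . import georeg, localemap, validity, varclus
from .errors import ErmimapError
from .panel import load_panel
from .synth import HomeMatrix, SynthConfig, generate

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("ermimap")

_STAGES = ("synth", "scan", "locales")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    if stage not in _STAGES:
        raise ErmimapError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([root_seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; see module docstring for stage order."""

    input: str | None = None            # homes CSV; None -> synthesize
    synth: SynthConfig = field(default_factory=SynthConfig)
    alpha: float = 0.05
    ks: tuple[int, ...] = tuple(range(2, 11))
    metrics: tuple[str, ...] = validity.METRICS
    algorithms: tuple[str, ...] = validity.ALGORITHMS
    scan_threshold: float = 0.25
    max_eig2: float = 1.0
    n_locales: int = 82
    n_classes: int = 5
    log_floor: float = 1.0
    seed: int = 0
    outdir: str = "ermimap_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cfg = cls(synth=synth, **raw)
        cfg.synth.seed = stage_seed(cfg.seed, "synth")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d["synth"].items()
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    The manifest records the config, the root seed and a sha256 per output
    file; identical (config, seed) pairs produce identical manifests.  A
    failing stage leaves a ``<stage>.partial`` marker in the output
    directory and re-raises with the stage name attached.
    """
    outdir = Path(config.outdir)
    if config.input is not None and not Path(config.input).exists():
        raise ErmimapError(f"input file not found: {config.input}")
    outdir.mkdir(parents=True, exist_ok=True)
    panel = load_panel()
    files: dict[str, Path] = {}
    stage = "init"
    log.info(
        "defaults in effect: log_floor=%s, population-sd standardization, "
        "tie-to-lower quartiles/classes, varclus ties to lower cluster id",
        config.log_floor,
    )
    try:
        stage = "synth"
        if config.input is None:
            cfg = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "synth"))
            homes = generate(cfg, panel)
        else:
            homes = HomeMatrix.from_csv(config.input)
        files["homes"] = outdir / "homes.csv"
        homes.to_csv(files["homes"])

        stage = "ermi"
        logm = ermi_mod.log_transform(homes.conc, log_floor=config.log_floor)
        indices = ermi_mod.compute_ermi(logm, panel)
        ermi_out = indices.copy()
        ermi_out.insert(0, "home_id", homes.home_ids)
        ermi_out["quartile"] = ermi_mod.ermi_quartiles(indices["ermi"])
        files["ermi"] = outdir / "ermi.csv"
        ermi_out.to_csv(files["ermi"], index=False)

        stage = "georeg"
        fits = georeg.fit_all(homes, panel, log_floor=config.log_floor)
        n1, n2 = georeg.significance_counts(fits, panel, alpha=config.alpha)
        log.info("significant species at alpha=%.3g: %d Group 1, %d Group 2",
                 config.alpha, n1, n2)
        files["regression"] = outdir / "regression.csv"
        fits.to_csv(files["regression"], index=False)

        stage = "scan"
        z = validity.standardize(logm)
        scan = validity.validity_scan(
            z, ks=config.ks, metrics=config.metrics,
            algorithms=config.algorithms,
            seed=stage_seed(config.seed, "scan"),
            threshold=config.scan_threshold,
        )
        files["validity_scan"] = outdir / "validity_scan.csv"
        scan.to_csv(files["validity_scan"], index=False)

        stage = "varclus"
        vc = varclus.varclus(z, max_eig2=config.max_eig2)
        tab = vc.table.copy()
        tab["group"] = [panel.resolve(s).group for s in tab["species"]]
        tab = tab[["species", "cluster", "group", "r2_own", "r2_next"]]
        files["clusters"] = outdir / "clusters.csv"
        tab.to_csv(files["clusters"], index=False)
        scores = vc.fpc_scores.copy()
        scores.insert(0, "home_id", homes.home_ids)
        files["fpc_scores"] = outdir / "fpc_scores.csv"
        scores.to_csv(files["fpc_scores"], index=False)

        stage = "locales"
        labels = localemap.assign_locales(
            homes.latitude, homes.longitude, n_locales=config.n_locales,
            seed=stage_seed(config.seed, "locales"),
        )
        values = vc.fpc_scores.copy()
        values["latitude"] = homes.latitude
        values["longitude"] = homes.longitude
        values[["slg1", "slg2", "ermi"]] = indices[["slg1", "slg2", "ermi"]].to_numpy()
        summaries = localemap.aggregate(values, labels, n_locales=config.n_locales)
        files["locales"] = outdir / "locales.csv"
        summaries.to_csv(files["locales"], index=False)
        layer_vars = [f"FPC{c.cluster_id}" for c in vc.clusters] + ["slg1", "slg2", "ermi"]
        for var in layer_vars:
            cls = localemap.jenks_breaks(
                summaries[var].to_numpy(), n_classes=config.n_classes, variable=var
            )
            for fmt, suffix in (("geojson", "geojson"), ("csv", "csv")):
                key = f"layer_{var}_{suffix}"
                files[key] = outdir / f"layer_{var}.{suffix}"
                localemap.export_layer(summaries, cls, files[key], format=fmt)
    except Exception as exc:
        (outdir / f"{stage}.partial").write_text(
            f"pipeline failed during stage {stage!r}: {exc}\n"
        )
        raise ErmimapError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "n_map_layers": sum(1 for k in files if k.startswith("layer_") and k.endswith("_geojson")),
        "files": {k: _sha256(p) for k, p in sorted(files.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
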