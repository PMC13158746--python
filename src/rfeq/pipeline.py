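"""End-to-end analysis orchestration.

One call runs: retailer scoring -> buffer re-scoring -> rural/urban
contrasts -> count-model IRRs -> subsampling robustness -> spatial
inference (Moran, LISA, Ripley's K), writing one CSV per stage plus a
machine-readable run manifest (package versions, seed, parameters). Each
stage draws its randomness from a seed spawned deterministically from the
run seed, so identical inputs and config yield byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import load_catalog
from .contrasts import contrasts_to_frame, group_contrasts, summarize_environment
from .indices import INDEX_COLUMNS
from .io import read_retailers, read_window, write_scored_table, StudyWindow
from .neighborhood import BufferSpec, score_buffers
from .projection import project_to_plane
from .regression import fit_count_model
from .robustness import subsample_means
from .spatial import build_weights, global_moran, lisa, ripley_k
from .synth import generate_environment, preset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("rfeq")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str
    retailers_path: Optional[str] = None  # or use a synthetic preset
    synth_preset: Optional[str] = None
    synth_n: Optional[int] = None
    window_path: Optional[str] = None
    catalog_path: Optional[str] = None
    radii: tuple[float, ...] = (50.0, 100.0, 200.0)
    family: str = "poisson"
    outcomes: tuple[str, ...] = INDEX_COLUMNS
    robustness_fraction: float = 0.7
    robustness_reps: int = 10_000
    weights_scheme: str = "k_nearest"
    weights_parameter: float = 8
    permutations: int = 999
    simulations: int = 199
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.retailers_path is None) == (self.synth_preset is None):
            raise ValueError(
                "exactly one of retailers_path or synth_preset is required"
            )
        for name in ("retailers_path", "catalog_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    seed_of = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("synth", "robustness", "moran", "lisa", "ripley", "fisher"), seeds
        )
    }
    catalog = load_catalog(config.catalog_path)
    artifacts: dict[str, str] = {}

    # --- input ---------------------------------------------------------
    window: Optional[StudyWindow] = None
    if config.synth_preset is not None:
        cfg = preset(config.synth_preset, n_outlets=config.synth_n,
                     seed=seed_of["synth"])
        records, _truth = _stage("synth")(generate_environment)(cfg, catalog)
        window = cfg.window
        # the synthetic window lives in the anchor's tangent plane
        points = _stage("project")(project_to_plane)(
            records, origin=cfg.anchor_lonlat
        )
    else:
        records = _stage("read")(read_retailers)(config.retailers_path, catalog)
        points = _stage("project")(project_to_plane)(records)

    # --- scoring + buffers --------------------------------------------
    spec = BufferSpec(radii=tuple(float(r) for r in config.radii))
    scored = _stage("score")(score_buffers)(records, spec, catalog, points)
    p = outdir / "scored.csv"
    write_scored_table(scored, p)
    artifacts["scored"] = str(p)

    # --- contrasts -----------------------------------------------------
    if scored["stratum"].nunique() == 2:
        results = _stage("contrast")(group_contrasts)(scored)
        p = outdir / "contrasts.csv"
        contrasts_to_frame(results).to_csv(p, index=False, float_format="%.6g")
        artifacts["contrasts"] = str(p)

    summary = _stage("describe")(summarize_environment)(scored)

    # --- regression ----------------------------------------------------
    covariates = ["shelf_space", "gender", "typology"]
    if scored["stratum"].nunique() == 2:
        covariates = ["stratum"] + covariates
    for outcome in config.outcomes:
        irr = _stage("regress")(fit_count_model)(
            scored, outcome=outcome, covariates=covariates, family=config.family
        )
        p = outdir / f"irr_{outcome}.csv"
        irr.to_csv(p)
        artifacts[f"irr_{outcome}"] = str(p)

    # --- robustness ----------------------------------------------------
    robustness_summaries = {}
    for outcome in config.outcomes:
        dist = _stage("robustness")(subsample_means)(
            scored,
            outcome=outcome,
            fraction=config.robustness_fraction,
            reps=config.robustness_reps,
            seed=seed_of["robustness"],
        )
        p = outdir / f"robustness_{outcome}.csv"
        dist.histogram().to_csv(p, index=False, float_format="%.6g")
        artifacts[f"robustness_{outcome}"] = str(p)
        robustness_summaries[outcome] = dist.summary()

    # --- spatial -------------------------------------------------------
    weights = _stage("weights")(build_weights)(
        points, scheme=config.weights_scheme, parameter=config.weights_parameter
    )
    moran_rows = []
    for outcome in config.outcomes:
        m = _stage("moran")(global_moran)(
            scored[outcome].to_numpy(float), weights,
            permutations=config.permutations, seed=seed_of["moran"],
        )
        moran_rows.append(
            {
                "outcome": outcome,
                "moran_i": m.I,
                "expected_i": m.expected_i,
                "p_value": m.p_value,
                "permutations": m.permutations,
                "seed": m.seed,
                "weights": f"{config.weights_scheme}({config.weights_parameter:g})",
            }
        )
        li = _stage("lisa")(lisa)(
            scored[outcome].to_numpy(float), weights,
            permutations=config.permutations, seed=seed_of["lisa"],
            alpha=config.alpha,
        )
        lf = li.to_frame()
        lf.insert(0, "id", scored["id"].to_numpy())
        p = outdir / f"lisa_{outcome}.csv"
        lf.to_csv(p, index=False, float_format="%.6g")
        artifacts[f"lisa_{outcome}"] = str(p)
    p = outdir / "moran.csv"
    pd.DataFrame(moran_rows).to_csv(p, index=False, float_format="%.6g")
    artifacts["moran"] = str(p)

    if window is None:
        if config.window_path is None:
            logger.info("no study window supplied; skipping the K function")
        else:
            window = _stage("kfunction")(read_window)(config.window_path)
            # window files are lon/lat; project with the same origin as points
            lonlat = np.array([[r.lon, r.lat] for r in records])
            origin = (float(lonlat[:, 0].mean()), float(lonlat[:, 1].mean()))
            from .projection import lonlat_to_enu
            from shapely import ops as shapely_ops

            window = StudyWindow(
                polygon=shapely_ops.transform(
                    lambda x, y: tuple(
                        lonlat_to_enu(np.column_stack([x, y]), origin).T
                    ),
                    window.polygon,
                ),
                crs_note="local ENU meters about the record centroid",
            )
    if window is not None:
        env = _stage("kfunction")(ripley_k)(
            points, window, simulations=config.simulations, seed=seed_of["ripley"]
        )
        p = outdir / "kfunction.csv"
        env.to_frame().to_csv(p, index=False, float_format="%.6g")
        artifacts["kfunction"] = str(p)
        k_summary = {
            "z_max": env.z_max,
            "r_peak": env.r_peak,
            "simulations": env.simulations,
            "rank": env.rank,
        }
    else:
        k_summary = None

    manifest = {
        "package": {"name": "rfeq", "version": __version__},
        "versions": _library_versions(),
        "seed": config.seed,
        "stage_seeds": seed_of,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "summary": summary,
        "robustness": robustness_summaries,
        "kfunction": k_summary,
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _library_versions() -> dict:
    import scipy
    import shapely
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
        "statsmodels": statsmodels.__version__,
    }
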