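"""End-to-end study orchestration: simulate/read -> segment -> fit -> report.

A `StudyConfig` (JSON-friendly dict) names the input source — step-length
files, trajectory files, or a simulation block — plus segmentation
thresholds, the candidate model list and the truncation-bounds policy.
`run_study` executes the stages in order and writes a report bundle:

* a per-individual fit table (one row per individual: n, fitted D, the
  log-likelihood of every candidate family, and the pairwise Akaike
  weight of the constrained GSE against the bi-exponential and the
  unconstrained GSE),
* a per-condition table with pooled fits and multi-model Akaike weights,
* the across-individual exact binomial sign test,
* rank-frequency curves per condition, and
* a JSON run log with seeds and the config hash.

All defaults equal the study's analysis choices: 45 degree turn
threshold, 4 cm minimum run, 4 m radius cap, AICc weights, exact binomial
test.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .families import SupportBounds, FAMILIES
from .fitting import (
    FitResult,
    InsufficientStepsError,
    StepSample,
    aicc,
    fit,
    multi_model_weights,
    pairwise_weight,
    rank_frequency,
    sign_test,
)
from .segmentation import PathSegmenter
from .simulate import WalkerConfig, quadrant_fractal, simulate_walker, uniform_field

logger = logging.getLogger("stepcue")

__all__ = ["StudyConfig", "ReportBundle", "run_study"]

DEFAULT_MODELS = ["EXP", "BIEXP", "GSE_CONSTRAINED", "GSE_FREE", "POWER"]


@dataclass
class StudyConfig:
    """Validated study configuration (see module docstring)."""

    out_dir: str
    steps_path: str | None = None
    trajectories_path: str | None = None
    simulate: dict | None = None
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    bounds_policy: str = "data"  # or "delta" (simulation only)
    angle_threshold_deg: float = 45.0
    min_run_m: float = 0.04
    radius_cap_m: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in FAMILIES:
                raise ValueError(f"unknown model name {m!r}")
        if self.bounds_policy not in ("data", "delta"):
            raise ValueError("bounds_policy must be 'data' or 'delta'")
        if min(self.angle_threshold_deg, self.min_run_m, self.radius_cap_m) <= 0:
            raise ValueError("segmentation thresholds must be positive")
        sources = [self.steps_path, self.trajectories_path, self.simulate]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of steps_path / trajectories_path / simulate required"
            )
        for p in (self.steps_path, self.trajectories_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    individual_table: pd.DataFrame
    condition_table: pd.DataFrame
    sign_test_p: float | None
    n_above_half: int | None
    n_fitted: int
    n_refused: int
    rank_frequency: dict[str, pd.DataFrame]
    run_log: dict


def _simulate_samples(cfg: StudyConfig) -> tuple[list[StepSample], dict[str, float]]:
    """One simulated walker per (condition, seed); returns samples and deltas."""
    samples: list[StepSample] = []
    deltas: dict[str, float] = {}
    for condition, spec in cfg.simulate.items():
        kind = spec.get("field", "uniform")
        n_steps = int(spec.get("n_steps", 500))
        seeds = spec.get("seeds") or [cfg.seed or 0]
        for s in seeds:
            if kind == "uniform":
                fld = uniform_field(
                    density=float(spec.get("density", 60.0)),
                    domain=float(spec.get("domain", 8.0)),
                    rho=float(spec["rho"]) if "rho" in spec else 0.01,
                    seed=int(s),
                )
            elif kind == "quadrant-fractal":
                fld = quadrant_fractal(
                    levels=int(spec.get("levels", 8)),
                    domain=float(spec.get("domain", 8.0)),
                    rho=float(spec["rho"]) if "rho" in spec else None,
                    seed=int(s),
                )
            else:
                raise ValueError(f"unknown field kind {kind!r}")
            deltas[condition] = fld.delta
            _, sample = simulate_walker(
                fld, WalkerConfig(max_steps=n_steps, seed=int(s) + 1)
            )
            lengths = sample.lengths
            if cfg.bounds_policy == "delta":
                lengths = lengths[lengths >= fld.delta]
            samples.append(
                StepSample(lengths, individual=f"{condition}-{s}",
                           condition=condition)
            )
    return samples, deltas


def _segment_samples(cfg: StudyConfig) -> list[StepSample]:
    trajs = sio.read_trajectories(cfg.trajectories_path)
    seg = PathSegmenter(
        angle_threshold_deg=cfg.angle_threshold_deg,
        min_run=cfg.min_run_m,
        radius_cap=cfg.radius_cap_m,
    )
    samples = []
    for t in trajs:
        lengths = np.array([s.length for s in seg.transform(t)], dtype=float)
        lengths = lengths[lengths > 0]
        if lengths.size:
            samples.append(
                StepSample(lengths, individual=t.id, condition=t.condition)
            )
    return samples


def _bounds_for(cfg: StudyConfig, sample: StepSample,
                deltas: dict[str, float]) -> SupportBounds | None:
    if cfg.bounds_policy == "delta" and sample.condition in deltas:
        domain = 8.0
        if cfg.simulate and sample.condition in cfg.simulate:
            domain = float(cfg.simulate[sample.condition].get("domain", 8.0))
        upper = max(domain * math.sqrt(2.0), float(sample.lengths.max()))
        return SupportBounds(deltas[sample.condition], upper)
    return None  # data-driven bounds


def run_study(cfg: StudyConfig) -> ReportBundle:
    """Execute all stages and write the report bundle under cfg.out_dir."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    # ---- stage: acquire samples ------------------------------------------
    t = time.time()
    deltas: dict[str, float] = {}
    try:
        if cfg.steps_path:
            samples = sio.read_step_lengths(cfg.steps_path)
        elif cfg.trajectories_path:
            samples = _segment_samples(cfg)
        else:
            samples, deltas = _simulate_samples(cfg)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'acquire' failed: {exc}") from exc
    if not samples:
        raise RuntimeError("stage 'acquire' produced no samples")
    stage_times["acquire"] = time.time() - t

    # ---- stage: per-individual fits --------------------------------------
    t = time.time()
    rows = []
    fits_by_ind: dict[str, dict[str, FitResult]] = {}
    n_refused = 0
    for s in samples:
        bounds = _bounds_for(cfg, s, deltas)
        row: dict = {"id": s.individual, "condition": s.condition, "n": s.n}
        fits: dict[str, FitResult] = {}
        for fam in cfg.models:
            try:
                fits[fam] = fit(s, fam, bounds=bounds)
                row[f"logl_{fam.lower()}"] = fits[fam].log_likelihood
            except InsufficientStepsError:
                row[f"logl_{fam.lower()}"] = np.nan
        if not fits:
            n_refused += 1
            logger.info("individual %s refused: too few steps (n=%d)",
                        s.individual, s.n)
        if "GSE_CONSTRAINED" in fits:
            row["D_hat"] = fits["GSE_CONSTRAINED"].model.params["D"]
            for other, col in (("BIEXP", "w_gse_vs_biexp"),
                               ("GSE_FREE", "w_gse_vs_free")):
                if other in fits:
                    row[col] = pairwise_weight(fits["GSE_CONSTRAINED"], fits[other])
        rows.append(row)
        fits_by_ind[str(s.individual)] = fits
    individual_table = pd.DataFrame(rows)
    stage_times["fit_individuals"] = time.time() - t

    # ---- stage: sign test across individuals ------------------------------
    p_sign, n_above = None, None
    if "w_gse_vs_biexp" in individual_table:
        w = individual_table["w_gse_vs_biexp"].dropna()
        if len(w):
            n_above = int((w > 0.5).sum())
            p_sign = sign_test(n_above, len(w))

    # ---- stage: pooled per-condition fits and multi-model weights ---------
    t = time.time()
    cond_rows = []
    rf: dict[str, pd.DataFrame] = {}
    for condition in sorted({str(s.condition) for s in samples}):
        members = [s for s in samples if str(s.condition) == condition]
        pool = StepSample(np.concatenate([m.lengths for m in members]),
                          individual="pooled", condition=condition)
        bounds = _bounds_for(cfg, pool, deltas)
        pooled: dict[str, FitResult] = {}
        for fam in cfg.models:
            try:
                pooled[fam] = fit(pool, fam, bounds=bounds)
            except InsufficientStepsError:
                pass
        row = {"condition": condition, "n": pool.n}
        if "GSE_CONSTRAINED" in pooled:
            row["D_hat"] = pooled["GSE_CONSTRAINED"].model.params["D"]
        if len(pooled) >= 2:
            comp = multi_model_weights(list(pooled.values()))
            for f_, w_ in zip(comp.fits, comp.weights):
                row[f"w_{f_.model.family.lower()}"] = float(w_)
        cond_rows.append(row)
        lens, frac = rank_frequency(pool)
        rf[condition] = pd.DataFrame({"length_m": lens, "fraction_ge": frac})
    condition_table = pd.DataFrame(cond_rows)
    stage_times["fit_conditions"] = time.time() - t

    # ---- stage: write outputs ---------------------------------------------
    t = time.time()
    _check_consistency(individual_table, cfg.models)
    individual_table.to_csv(out / "individual_fits.tsv", sep="\t", index=False)
    condition_table.to_csv(out / "condition_fits.tsv", sep="\t", index=False)
    for condition, df in rf.items():
        df.to_csv(out / f"rank_frequency_{condition}.csv", index=False)
    run_log = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "models": cfg.models,
        "n_individuals": len(samples),
        "n_refused": n_refused,
        "sign_test_p": p_sign,
        "n_above_half": n_above,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "total_seconds": round(time.time() - t0, 3),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    stage_times["write"] = time.time() - t
    logger.info("study complete in %.1fs (%s)", time.time() - t0, cfg.digest())

    return ReportBundle(
        individual_table=individual_table,
        condition_table=condition_table,
        sign_test_p=p_sign,
        n_above_half=n_above,
        n_fitted=len(samples) - n_refused,
        n_refused=n_refused,
        rank_frequency=rf,
        run_log=run_log,
    )


def _check_consistency(table: pd.DataFrame, models: list[str]) -> None:
    """Every written row must recompute its own AICc from logL, k, n."""
    for fam in models:
        col = f"logl_{fam.lower()}"
        if col not in table:
            continue
        k = FAMILIES[fam].k
        for _, r in table.dropna(subset=[col]).iterrows():
            if r["n"] > k + 1:
                val = aicc(float(r[col]), k, int(r["n"]))
                if not math.isfinite(val):
                    raise RuntimeError("inconsistent AICc in report table")
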