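"""Synthetic camera-trap surveys with the structure the analysis assumes.

The generator is the model run forward on a survey design emulating the
source study: 102 camera sites on a jittered grid, contiguous deployments
averaging 153 active days (SD 18, occasional mid-deployment outages),
distances to roads/settlements uniform on 305-4142 m, right-skewed human
activity and zero-inflated cattle activity.  Latent occupancy states and
occasion-level detections are drawn from the conditional two-species model;
each occasion-level detection is then materialized as a burst of camera
images (3 frames, 10 s apart — the camera protocol) placed so that the
30-minute independence filter and the occasion builder recover the latent
detection history *exactly*: bursts occupy distinct day x hour slots with
start minutes <= 20, so within-burst gaps are seconds and between-burst gaps
are always > 30 minutes.

Human and cattle streams are marginal site-level Poisson processes at the
site's RH/RC rates, so the covariates can be reconstructed from the records
by the same independence filter the field data went through.  The human
event count is floored at one per site, reflecting the study design in which
every site saw some human activity (naive occupancy 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import DesignMatrix, prepare_covariates
from .model import HYPOTHESES, HypothesisSpec, ParamSet, link_probabilities
from .records import Deployment, DetectionHistory, build_occasions

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "default_survey_config",
    "simulate_histories",
    "generate_dataset",
]

_MINUTES_SLOT_MAX = 20  # event start minute within its hour slot


def _default_prey_params() -> dict[str, dict[str, list[float]]]:
    # coefficient truth per prey on the logit scale (order: see model blocks);
    # intercepts give psi^B ~ 0.93, p^B ~ 0.4 (leopard absent), r^B ~ 0.65
    # (leopard present); slopes mimic the directions reported for human and
    # cattle activity
    return {
        "roe_deer": {
            "psiB": [2.6, 0.15, 0.1],
            "pB": [-0.41, 0.0, 0.1, 0.25, -0.6],
            "rB": [0.62, 0.1, 0.0, -0.23, -0.32],
        },
        "wild_boar": {
            "psiB": [2.7, -0.1, 0.1],
            "pB": [-0.45, 0.1, 0.0, 0.2, -0.4],
            "rB": [0.45, 0.0, 0.1, -0.2, -0.25],
        },
    }


@dataclass
class SimConfig:
    """Study-design and truth settings for the generator.

    Defaults emulate the source survey: 102 sites, mean effort 153
    camera-days (SD 18), 10-day occasions, DR/DS uniform on 305-4142 m,
    gamma-distributed human RAI around 1.5, cattle RAI zero-inflated (45%
    structural zeros) with a right-skewed positive part.
    """

    seed: int
    n_sites: int = 102
    mean_active_days: float = 153.0
    sd_active_days: float = 18.0
    occasion_length: int = 10
    gap_prob: float = 0.1  # chance of one mid-deployment outage (5-15 days)
    hypothesis: str = "H2"
    species_a: str = "leopard"
    # dominant-species truth
    psiA: list[float] = field(default_factory=lambda: [-0.24, 0.3, -0.2])
    pA: list[float] = field(default_factory=lambda: [-1.77, 0.1, -0.1, -0.15, -0.1])
    prey_params: Mapping[str, Mapping[str, list[float]]] = field(
        default_factory=_default_prey_params
    )
    # covariate generators
    dr_range: tuple[float, float] = (305.0, 4142.0)
    ds_range: tuple[float, float] = (305.0, 4142.0)
    lat0: float = 36.2
    lon0: float = 113.6
    grid_spacing_deg: float = 0.02  # ~2 km; jitter keeps >= 500 m separation
    rh_min: float = 0.3
    rh_shape: float = 1.3
    rh_mean: float = 1.4
    rc_zero_prob: float = 0.45
    rc_shape: float = 1.3
    rc_mean: float = 9.5
    # record emission
    images_per_event: int = 3
    burst_spacing_s: float = 10.0
    prey_extra_events: float = 0.7  # mean extra bursts per detected prey occasion
    start_date: date = date(2022, 9, 1)
    start_jitter_days: int = 30

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.occasion_length < 1:
            raise ValueError("occasion_length must be >= 1")
        if self.mean_active_days < self.occasion_length:
            raise ValueError("mean active days shorter than one occasion")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        for sp, blocks in self.prey_params.items():
            need = HYPOTHESES[self.hypothesis].b_vectors
            # prey coefficient dicts use canonical names psiB + the hypothesis's
            # detection vectors (pB/rB/rBa/rBA)
            missing = [v for v in ("psiB", *need) if v not in blocks]
            if missing:
                raise ValueError(f"prey {sp!r} missing coefficient vectors {missing}")

    def param_set(self, prey: str) -> ParamSet:
        """Generating ParamSet for the (species A, prey) pair."""
        hyp = HYPOTHESES[self.hypothesis]
        blocks = self.prey_params[prey]
        coef = {"psiA": np.asarray(self.psiA), "pA": np.asarray(self.pA),
                "psiB": np.asarray(blocks["psiB"])}
        for v in hyp.b_vectors:
            coef[v] = np.asarray(blocks[v])
        return ParamSet(hypothesis=hyp, coef=coef)


def default_survey_config(seed: int, **overrides) -> SimConfig:
    """The study-condition preset: expected naive occupancies near
    0.39 / 0.92 / 0.93 / 1.00 / 0.55 for leopard / roe deer / wild boar /
    human / cattle and RAI of the magnitudes the survey reported."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class SimTruth:
    """Everything the generator knew: latent states, latent detection
    matrices, the generating parameters and the hypothesis."""

    hypothesis: str
    params: dict[str, ParamSet]  # per prey
    z_a: np.ndarray
    z_b: dict[str, np.ndarray]
    hist_a: np.ndarray  # latent detection matrix of species A (NaN = no effort)
    hist_b: dict[str, np.ndarray]
    covariates: pd.DataFrame
    sites: list[str]

    def to_json_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "params": {k: v.to_dict() for k, v in self.params.items()},
            "z_a": self.z_a.tolist(),
            "z_b": {k: v.tolist() for k, v in self.z_b.items()},
            "sites": self.sites,
        }


# ---------------------------------------------------------------------------
# survey-design draws


def _draw_deployments(cfg: SimConfig, rng: np.random.Generator) -> list[Deployment]:
    deps = []
    width = len(str(cfg.n_sites))
    for i in range(cfg.n_sites):
        n_days = int(np.clip(round(rng.normal(cfg.mean_active_days, cfg.sd_active_days)),
                             max(30, cfg.occasion_length), 260))
        start = cfg.start_date + timedelta(int(rng.integers(0, cfg.start_jitter_days + 1)))
        end = start + timedelta(n_days - 1)
        inactive = []
        if rng.random() < cfg.gap_prob and n_days > 60:
            glen = int(rng.integers(5, 16))
            g0 = int(rng.integers(20, n_days - 20 - glen))
            inactive.append((start + timedelta(g0), start + timedelta(g0 + glen - 1)))
        deps.append(
            Deployment.from_interval(f"S{i + 1:0{width}d}", start, end, inactive)
        )
    return deps


def _draw_covariate_parts(cfg: SimConfig, rng: np.random.Generator, site_ids):
    n = len(site_ids)
    ncol = int(np.ceil(np.sqrt(n)))
    ii, jj = np.divmod(np.arange(n), ncol)
    jit = lambda: rng.uniform(-0.3, 0.3, n) * cfg.grid_spacing_deg
    lat = cfg.lat0 + ii * cfg.grid_spacing_deg + jit()
    lon = cfg.lon0 + jj * cfg.grid_spacing_deg + jit()
    rh_rate = cfg.rh_min + rng.gamma(cfg.rh_shape,
                                     (cfg.rh_mean - cfg.rh_min) / cfg.rh_shape, n)
    rc_rate = np.where(
        rng.random(n) < cfg.rc_zero_prob,
        0.0,
        rng.gamma(cfg.rc_shape, cfg.rc_mean / cfg.rc_shape, n),
    )
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "DR": rng.uniform(*cfg.dr_range, n),
            "DS": rng.uniform(*cfg.ds_range, n),
            "RH": rh_rate,
            "RC": rc_rate,
            "lat": lat,
            "lon": lon,
        }
    )


def _empty_histories(deps, cfg) -> DetectionHistory:
    return build_occasions([], deps, cfg.occasion_length, species="_effort_")


def _draw_latent(cfg: SimConfig, rng: np.random.Generator, dm: DesignMatrix, effort):
    """Latent occupancy states and occasion-level detection matrices."""
    hyp = HYPOTHESES[cfg.hypothesis]
    surveyed = effort > 0
    n, T = effort.shape

    paramsA = cfg.param_set(next(iter(cfg.prey_params)))
    pr = link_probabilities(paramsA, dm)
    z_a = (rng.random(n) < pr["psiA"]).astype(int)
    DA = np.where(
        surveyed, (rng.random((n, T)) < pr["pA"][:, None] * z_a[:, None]).astype(float), np.nan
    )

    z_b, DB = {}, {}
    for prey in cfg.prey_params:
        p = link_probabilities(cfg.param_set(prey), dm)
        zb = (rng.random(n) < p["psiB"]).astype(int)
        q = np.where(
            z_a[:, None] == 0,
            p["pB"][:, None],
            np.where(np.nan_to_num(DA) > 0, p["rBA"][:, None], p["rBa"][:, None]),
        )
        db = (rng.random((n, T)) < q * zb[:, None]).astype(float)
        DB[prey] = np.where(surveyed, db, np.nan)
        z_b[prey] = zb
    return z_a, DA, z_b, DB


def simulate_histories(cfg: SimConfig):
    """Fast path for replicate studies: latent detection histories and the
    design matrix, skipping record-stream emission.

    RH/RC covariates are the drawn site rates themselves (the full generator
    uses the realized RAI reconstructed from emitted records).

    Returns (hist_a, {prey: hist_b}, dm, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    deps = _draw_deployments(cfg, rng)
    site_ids = [d.site_id for d in deps]
    cov = _draw_covariate_parts(cfg, rng, site_ids)
    dm = prepare_covariates(cov)
    shell = _empty_histories(deps, cfg)
    z_a, DA, z_b, DB = _draw_latent(cfg, rng, dm, shell.effort)

    hist_a = DetectionHistory(cfg.species_a, site_ids, DA, shell.effort, cfg.occasion_length)
    hist_b = {
        prey: DetectionHistory(prey, site_ids, DB[prey], shell.effort, cfg.occasion_length)
        for prey in DB
    }
    truth = SimTruth(
        hypothesis=cfg.hypothesis,
        params={prey: cfg.param_set(prey) for prey in cfg.prey_params},
        z_a=z_a,
        z_b=z_b,
        hist_a=DA,
        hist_b=DB,
        covariates=cov,
        sites=site_ids,
    )
    return hist_a, hist_b, dm, truth


# ---------------------------------------------------------------------------
# record-stream emission


def _burst(site, species, day: date, slot: int, rng, cfg) -> list[dict]:
    minute = int(rng.integers(0, _MINUTES_SLOT_MAX + 1))
    second = int(rng.integers(0, 60))
    t0 = datetime.combine(day, time(slot, minute, second))
    return [
        {
            "site_id": site,
            "species": species,
            "timestamp": (t0 + timedelta(seconds=k * cfg.burst_spacing_s)).isoformat(),
        }
        for k in range(cfg.images_per_event)
    ]


def _place_bursts(site, species, days, n_events, rng, cfg) -> list[dict]:
    """Place n_events bursts on distinct (day, hour-slot) combos of the given
    active days; distinct combos guarantee inter-event gaps > 30 min."""
    combos = [(d, h) for d in days for h in range(24)]
    n_events = min(n_events, len(combos))
    pick = rng.choice(len(combos), size=n_events, replace=False)
    rows = []
    for idx in pick:
        d, h = combos[idx]
        rows += _burst(site, species, d, h, rng, cfg)
    return rows


@dataclass
class SimulatedDataset:
    """A full synthetic survey: raw record stream, deployment calendar,
    site covariates and the generating truth."""

    records: pd.DataFrame
    deployments: pd.DataFrame
    covariates: pd.DataFrame
    truth: SimTruth
    deployment_objects: list[Deployment] = field(repr=False, default_factory=list)

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.deployments.to_csv(out / "deployments.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth.to_json_dict(), fh, indent=1)


def generate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a complete synthetic survey as raw CSV-shaped tables.

    The animal detection probabilities are computed from the *realized*
    covariates (RAI of human and cattle reconstructed from the emitted
    streams), so running the full pipeline — independence filter, occasion
    builder, covariate preparation — reproduces the generating conditions
    exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    deps = _draw_deployments(cfg, rng)
    site_ids = [d.site_id for d in deps]
    cov = _draw_covariate_parts(cfg, rng, site_ids)
    shell = _empty_histories(deps, cfg)
    effort = shell.effort

    # human & cattle streams at the drawn rates; human count floored at 1
    rows: list[dict] = []
    realized = {"RH": [], "RC": []}
    for i, dep in enumerate(deps):
        days = list(dep.active_days)
        n_h = max(1, rng.poisson(cov.RH.iloc[i] * dep.effort / 100.0))
        n_c = rng.poisson(cov.RC.iloc[i] * dep.effort / 100.0)
        rows += _place_bursts(dep.site_id, "human", days, n_h, rng, cfg)
        rows += _place_bursts(dep.site_id, "cattle", days, n_c, rng, cfg)
        realized["RH"].append(100.0 * n_h / dep.effort)
        realized["RC"].append(100.0 * n_c / dep.effort)
    cov = cov.assign(RH=realized["RH"], RC=realized["RC"])

    dm = prepare_covariates(cov)
    z_a, DA, z_b, DB = _draw_latent(cfg, rng, dm, effort)

    # occasion -> active days lookup per site
    occ_days: list[list[list[date]]] = []
    for dep in deps:
        T = effort.shape[1]
        buckets: list[list[date]] = [[] for _ in range(T)]
        for day in dep.active_days:
            buckets[(day - dep.first_day).days // cfg.occasion_length].append(day)
        occ_days.append(buckets)

    for i, dep in enumerate(deps):
        for t in range(effort.shape[1]):
            days = occ_days[i][t]
            if not days:
                continue
            if DA[i, t] == 1.0:
                rows += _place_bursts(dep.site_id, cfg.species_a, days, 1, rng, cfg)
            for prey in DB:
                if DB[prey][i, t] == 1.0:
                    n_ev = 1 + rng.poisson(cfg.prey_extra_events)
                    rows += _place_bursts(dep.site_id, prey, days, n_ev, rng, cfg)

    records = (
        pd.DataFrame(rows, columns=["site_id", "species", "timestamp"])
        .sort_values(["site_id", "species", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    dep_rows = [
        {
            "site_id": d.site_id,
            "start_date": d.first_day.isoformat(),
            "end_date": d.last_day.isoformat(),
            "kind": "active",
        }
        for d in deps
    ]
    for d in deps:
        # recover inactive intervals as gaps in the active-day set
        all_days = {d.first_day + timedelta(k) for k in range((d.last_day - d.first_day).days + 1)}
        off = sorted(all_days - set(d.active_days))
        while off:
            a = b = off[0]
            while off and off[0] == b:
                off.pop(0)
                b = b + timedelta(1)
            dep_rows.append(
                {
                    "site_id": d.site_id,
                    "start_date": a.isoformat(),
                    "end_date": (b - timedelta(1)).isoformat(),
                    "kind": "inactive",
                }
            )

    truth = SimTruth(
        hypothesis=cfg.hypothesis,
        params={prey: cfg.param_set(prey) for prey in cfg.prey_params},
        z_a=z_a,
        z_b=z_b,
        hist_a=DA,
        hist_b=DB,
        covariates=cov,
        sites=site_ids,
    )
    return SimulatedDataset(
        records=records,
        deployments=pd.DataFrame(dep_rows),
        covariates=cov,
        truth=truth,
        deployment_objects=deps,
    )
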