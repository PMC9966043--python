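"""Synthetic three-arm atropine-trial generator.

Emulates the measurement structure the downstream analysis assumes: three
randomized arms (placebo / 0.01% atropine "low dose" / 0.1%-to-0.01%
"loading dose"), ~32-33 children per arm over 3 sites, visits at months
0/3/6, two highly correlated eyes per child, and per-outcome latent visit
trajectories drawn multivariate-normal around arm- and site-specific
means.  Default calibration: baseline means/SDs and arm-by-visit mean
changes of published low-dose-atropine trial tables for Danish children.

The generator simulates the *measured* quantities (AL, CCT, ACD, LT, ChT,
corneal power, and the latent spherical equivalent emitted as quality-
scored autorefractor readings); vitreous chamber depth and Bennett lens
power are derived downstream, so their treatment effects are implied by
the simulated segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError

VISIT_MONTHS = (0, 3, 6)
ARMS = ("placebo", "low_dose", "loading_dose")

#: Baseline mean and SD of each simulated outcome (whole-cohort column).
BASELINE = {
    "al_mm": (24.48, 0.84),
    "cct_um": (546.8, 30.3),
    "acd_mm": (3.31, 0.24),
    "lt_mm": (3.36, 0.17),
    "cht_um": (248.0, 66.2),
    "se_d": (-3.02, 1.27),
    "km_d": (43.7, 1.5),
}

#: Placebo-arm mean change from baseline at months (3, 6).
PLACEBO_CHANGE = {
    "al_mm": (0.10, 0.21),
    "cct_um": (2.2, 2.5),
    "acd_mm": (0.00, 0.01),
    "lt_mm": (0.01, -0.01),
    "cht_um": (0.5, -2.8),
    "se_d": (-0.20, -0.37),
    "km_d": (-0.04, -0.03),
}

#: Active-arm difference from the placebo change at months (3, 6).
ARM_DIFFERENCE = {
    "low_dose": {
        "al_mm": (-0.03, -0.06),
        "cct_um": (-2.3, -1.9),
        "acd_mm": (0.01, 0.02),
        "lt_mm": (-0.01, -0.01),
        "cht_um": (3.3, 2.0),
        "se_d": (0.17, 0.16),
        "km_d": (0.00, 0.01),
    },
    "loading_dose": {
        "al_mm": (-0.08, -0.13),
        "cct_um": (-1.1, 0.1),
        "acd_mm": (0.05, 0.05),
        "lt_mm": (-0.03, -0.02),
        "cht_um": (14.4, 12.8),
        "se_d": (0.34, 0.40),
        "km_d": (0.05, 0.01),
    },
}

#: Half-separation of the flattest/steepest corneal meridians around Km (D).
K_SPLIT = 0.45


def _ar1(sd: float, rho: float, t: int = 3) -> np.ndarray:
    lags = np.abs(np.subtract.outer(np.arange(t), np.arange(t)))
    return sd * sd * rho ** lags


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic trial.

    Defaults state the emulated study: 32/32/33 per arm, 3 sites, visit
    SDs equal to the baseline SD with lag-0.8 within-participant visit
    correlation, inter-eye correlation 0.98, additive site shifts of 0.1
    baseline-SD, and whole-visit MCAR dropout with probability 1/97 per
    follow-up visit (one withdrawal among 97).
    """

    n_per_arm: Tuple[int, int, int] = (32, 32, 33)
    arms: Tuple[str, ...] = ARMS
    n_sites: int = 3
    site_probs: Tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    outcomes: Tuple[str, ...] = tuple(BASELINE)
    baseline: Dict[str, Tuple[float, float]] = field(default_factory=lambda: dict(BASELINE))
    placebo_change: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(PLACEBO_CHANGE))
    arm_difference: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {a: dict(d) for a, d in ARM_DIFFERENCE.items()})
    visit_rho: float = 0.8
    visit_cov: Dict[str, np.ndarray] | None = None  # overrides visit_rho scaling
    inter_eye_rho: float = 0.98
    site_shift_sd: float = 0.1          # in units of each outcome's baseline SD
    missing_visit_prob: float = 1.0 / 97.0
    reading_noise_sd: float = 0.1       # per-reading sphere noise (D)
    cylinder_d: float = -0.50
    n_readings: int = 5
    seed: int = 20190501

    def __post_init__(self):
        if any(n < 2 for n in self.n_per_arm):
            raise ConfigError("need at least 2 participants per arm")
        if not np.isclose(sum(self.site_probs), 1.0):
            raise ConfigError("site probabilities must sum to 1")
        if not (0 <= self.missing_visit_prob <= 1):
            raise ConfigError("missing_visit_prob must lie in [0, 1]")
        if not (0 < self.inter_eye_rho <= 1):
            raise ConfigError("inter_eye_rho must lie in (0, 1]")
        for name in self.outcomes:
            np.linalg.cholesky(self.outcome_cov(name))  # raises if not PD

    def outcome_cov(self, name: str) -> np.ndarray:
        """3x3 within-participant visit covariance for one outcome."""
        if self.visit_cov and name in self.visit_cov:
            cov = np.asarray(self.visit_cov[name], dtype=float)
            if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
                raise ConfigError(f"visit_cov[{name}] must be symmetric 3x3")
            return cov
        sd = self.baseline[name][1]
        return _ar1(sd, self.visit_rho)

    def arm_change(self, arm: str, name: str) -> np.ndarray:
        """Mean change from baseline at months (0, 3, 6) for one arm."""
        d3, d6 = self.placebo_change[name]
        if arm != self.arms[0]:
            a3, a6 = self.arm_difference[arm][name]
            d3, d6 = d3 + a3, d6 + a6
        return np.array([0.0, d3, d6])

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_per_arm", "arms", "site_probs", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TrialDataset:
    """A simulated trial: raw long-format table plus generative truth."""

    data: pd.DataFrame
    truth: dict
    config: SimulationConfig


def _emit_refraction(rng: np.random.Generator, se_target: np.ndarray,
                     config: SimulationConfig):
    """Emit autorefractor reading stacks consistent with the target SE.

    Five quality-scored readings per measurement; per-reading sphere noise
    is centred over the qualifying (quality >= 7) subset so that the
    quality-filtered mean reproduces the latent SE exactly.  The first
    reading always qualifies.
    """
    shape = se_target.shape + (config.n_readings,)
    quality = rng.integers(5, 11, size=shape).astype(float)
    quality[..., 0] = np.maximum(quality[..., 0], 7.0)
    ok = quality >= 7.0
    noise = rng.normal(0.0, config.reading_noise_sd, size=shape)
    nok = ok.sum(axis=-1, keepdims=True)
    noise = noise - np.sum(noise * ok, axis=-1, keepdims=True) / nok
    cyl = np.full(shape, config.cylinder_d)
    sphere = se_target[..., None] - cyl / 2.0 + np.where(ok, noise, 1.0)
    return sphere, cyl, quality, ok


def simulate_trial(config: SimulationConfig | None = None,
                   seed: int | None = None) -> TrialDataset:
    """Draw one synthetic trial; identical (config, seed) is byte-identical.

    Per participant and outcome a 3-visit latent trajectory is drawn
    MVN(baseline + arm change + site shift, visit_cov); two eye-level
    values are drawn around the latent trajectory with marginal inter-eye
    correlation ``inter_eye_rho``; refraction is emitted as quality-scored
    readings whose filtered mean equals the latent SE.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_total = sum(config.n_per_arm)
    arm_idx = np.repeat(np.arange(len(config.arms)), config.n_per_arm)
    site = rng.choice(np.arange(1, config.n_sites + 1), size=n_total,
                      p=np.asarray(config.site_probs))
    months = np.asarray(VISIT_MONTHS)

    eye_vals: Dict[str, np.ndarray] = {}
    site_shifts = {}
    for name in config.outcomes:
        mu0, sd = config.baseline[name]
        cov = config.outcome_cov(name)
        chol = np.linalg.cholesky(cov)
        shift = rng.normal(0.0, config.site_shift_sd * sd, size=config.n_sites)
        site_shifts[name] = shift
        change = np.stack([config.arm_change(a, name) for a in config.arms])
        mean = mu0 + change[arm_idx] + shift[site - 1][:, None]      # (n, 3)
        latent = mean + rng.standard_normal((n_total, 3)) @ chol.T
        # total eye-level variance v + ve with ve = v*(1-rho)/rho gives
        # corr(OD, OS) = rho marginally at each visit
        var_e = np.diag(cov) * (1.0 - config.inter_eye_rho) / config.inter_eye_rho
        noise = rng.normal(0.0, 1.0, size=(n_total, 3, 2)) * np.sqrt(var_e)[None, :, None]
        eye_vals[name] = latent[:, :, None] + noise                   # (n, 3, 2)

    nan_block = np.full((n_total, 3, 2), np.nan)
    if "se_d" in eye_vals:
        sphere, cyl, quality, ok = _emit_refraction(rng, eye_vals["se_d"], config)
        sph_avg = np.sum(sphere * ok, axis=-1) / ok.sum(axis=-1)
        qual_max = quality.max(axis=-1)
        cyl_col = np.full(n_total * 6, config.cylinder_d)
    else:
        sph_avg = qual_max = nan_block
        cyl_col = np.full(n_total * 6, np.nan)

    pid = np.array([f"P{i + 1:04d}" for i in range(n_total)])
    rows = {
        "pid": np.repeat(pid, 6),
        "site": np.repeat(site, 6),
        "arm": np.repeat(np.asarray(config.arms)[arm_idx], 6),
        "month": np.tile(np.repeat(months, 2), n_total),
        "eye": np.tile(["OD", "OS"], n_total * 3),
    }
    for name in ("al_mm", "cct_um", "acd_mm", "lt_mm", "cht_um"):
        rows[name] = eye_vals.get(name, nan_block).reshape(-1)
    km = eye_vals.get("km_d", nan_block)
    rows["k1_d"] = (km - K_SPLIT).reshape(-1)
    rows["k2_d"] = (km + K_SPLIT).reshape(-1)
    rows["sphere_d"] = sph_avg.reshape(-1)
    rows["cylinder_d"] = cyl_col
    rows["quality"] = qual_max.reshape(-1)
    data = pd.DataFrame(rows)

    truth = {
        "arms": list(config.arms),
        "placebo_change": {k: list(v) for k, v in config.placebo_change.items()},
        "arm_difference": {a: {k: list(v) for k, v in d.items()}
                           for a, d in config.arm_difference.items()},
        "visit_cov": {k: config.outcome_cov(k).tolist() for k in config.outcomes},
        "inter_eye_rho": config.inter_eye_rho,
        "site_shifts": {k: v.tolist() for k, v in site_shifts.items()},
    }
    ds = TrialDataset(data=data, truth=truth, config=config)
    return inject_missingness(ds, config, rng)


def inject_missingness(dataset: TrialDataset, config: SimulationConfig | None = None,
                       rng: np.random.Generator | None = None) -> TrialDataset:
    """Remove whole follow-up visits by monotone MCAR dropout.

    Each participant drops out before month 3 with probability
    ``missing_visit_prob`` and, if still in, before month 6 with the same
    probability; a dropped visit removes both eyes' rows.  Baseline is
    never removed (participants are enrolled at baseline).
    """
    config = config or dataset.config
    p = config.missing_visit_prob
    if p == 0:
        return dataset
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    data = dataset.data
    pids = data["pid"].unique()
    u = rng.random((len(pids), 2))
    drop3 = u[:, 0] < p
    drop6 = drop3 | (u[:, 1] < p)      # monotone dropout
    drop_map3 = dict(zip(pids, drop3))
    drop_map6 = dict(zip(pids, drop6))
    month = data["month"].to_numpy()
    kill = ((month == 3) & data["pid"].map(drop_map3).to_numpy()) | \
           ((month == 6) & data["pid"].map(drop_map6).to_numpy())
    return TrialDataset(data=data.loc[~kill].reset_index(drop=True),
                        truth=dataset.truth, config=config)


def simulate_mediation_system(n_per_arm: int = 500,
                              beta: Dict[str, Dict[str, float]] | None = None,
                              gamma: Dict[str, float] | None = None,
                              direct: Dict[str, float] | None = None,
                              mediator_sd: Dict[str, float] | None = None,
                              residual_sd: float = 0.35,
                              arms: Sequence[str] = ARMS,
                              seed: int = 0) -> pd.DataFrame:
    """Draw change-score data from an explicit linear mediation system.

    Mediator changes are ``d_m = beta0 + beta[m][arm] + e_m`` and the
    outcome change is ``d_se = a + direct[arm] + sum_m gamma[m]*d_m + e``.
    Default coefficients are on the scale of a 3-month atropine effect
    (AL in mm, LP in D, ChT in mm).  Returns a complete-case change table
    ready for :class:`ocutrial.mediation.MediationModel`.
    """
    beta = beta or {
        "d_al_mm": {"low_dose": -0.03, "loading_dose": -0.08},
        "d_lp_d": {"low_dose": -0.03, "loading_dose": -0.09},
        "d_cht_mm": {"low_dose": 0.004, "loading_dose": 0.014},
    }
    gamma = gamma or {"d_al_mm": -2.8, "d_lp_d": -1.0, "d_cht_mm": 0.9}
    direct = direct or {"low_dose": 0.02, "loading_dose": -0.01}
    mediator_sd = mediator_sd or {"d_al_mm": 0.05, "d_lp_d": 0.30, "d_cht_mm": 0.02}
    rng = np.random.default_rng(seed)
    arm = np.repeat(list(arms), n_per_arm)
    n = len(arm)
    out = {"arm": arm}
    d_se = rng.normal(-0.20, residual_sd, size=n)
    for m, g in gamma.items():
        base = {"d_al_mm": 0.10, "d_lp_d": -0.05, "d_cht_mm": 0.0005}.get(m, 0.0)
        eff = np.array([beta[m].get(a, 0.0) for a in arm])
        dm = base + eff + rng.normal(0.0, mediator_sd[m], size=n)
        out[m] = dm
        d_se = d_se + g * dm
    d_se = d_se + np.array([direct.get(a, 0.0) for a in arm])
    out["d_se_d"] = d_se
    return pd.DataFrame(out)


def write_trial(dataset: TrialDataset, csv_path, truth_path=None) -> None:
    """Write the long-format CSV and, optionally, a JSON truth sidecar."""
    dataset.data.to_csv(csv_path, index=False)
    if truth_path is not None:
        import json
        with open(truth_path, "w") as fh:
            json.dump({"truth": dataset.truth,
                       "config": {k: v for k, v in asdict(dataset.config).items()
                                  if not isinstance(v, np.ndarray)}},
                      fh, indent=2, default=str)
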