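"""Synthetic nested case-control cohort generator.

Emulates the structure of a pre-diagnostic serum study: 143 post-menopausal
case subjects (some with 2-6 annual longitudinal draws, 218+ case samples),
249 matched controls, ~101 biomarkers measured per sample, covariates whose
population odds ratios match configured targets, and per-marker censoring at
the assay limit of detection.

Marker kinetics: for a case sample drawn t years before diagnosis, the
log-concentration of marker m is shifted by delta_m * exp(-t / tau_m) — an
exponential rise toward diagnosis, the simplest shape consistent with
serological markers rising ahead of clinical presentation.  Controls sit at
the baseline log-normal.  An optional Gaussian copula induces equicorrelated
markers so that ensemble diversity downstream is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError

__all__ = ["MarkerEffect", "SimulationConfig", "simulate_cohort", "simulate_external_set"]


@dataclass(frozen=True)
class MarkerEffect:
    name: str
    delta: float  # log-scale case shift at diagnosis
    tau: float = 1.5  # e-folding timescale, years

    def shift(self, ytd_years: np.ndarray) -> np.ndarray:
        return self.delta * np.exp(-np.asarray(ytd_years) / self.tau)


def _default_effects() -> tuple[MarkerEffect, ...]:
    # Magnitudes chosen to give strong-to-moderate single-marker separation
    # near diagnosis, fading with years to diagnosis.
    return (
        MarkerEffect("CA19-9", 2.0, 1.5),
        MarkerEffect("MUC16", 1.2, 1.5),
        MarkerEffect("THBS2", 1.0, 2.0),
        MarkerEffect("CEACAM5", 0.9, 1.5),
        MarkerEffect("VWF", 0.7, 2.0),
        MarkerEffect("IL6ST", 0.6, 2.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults mirror the discovery cohort's totals."""

    n_cases: int = 143
    n_controls: int = 249
    longitudinal_fraction: float = 35.0 / 143.0
    longitudinal_draws: tuple[int, int] = (2, 6)
    n_markers: int = 101
    effects: tuple[MarkerEffect, ...] = field(default_factory=_default_effects)
    marker_corr: float = 0.2  # equicorrelation of log-markers
    marker_sigma: float = 1.0  # log-scale SD
    # covariate model (control-arm prevalences / means, case odds ratios & shifts)
    age_control_mean: float = 62.48
    age_case_shift: float = 64.94 - 62.48
    age_sd: float = 5.5
    bmi_control_mean: float = 26.64
    bmi_case_shift: float = 27.46 - 26.64
    bmi_sd: float = 4.5
    hrt_control_prev: float = 48.0 / 249.0
    hrt_or: float = 0.41
    ocp_control_prev: float = 127.0 / 249.0
    ocp_or: float = 1.47
    diabetes_control_prev: float = 11.0 / 249.0
    diabetes_or: float = 4.99
    max_ytd_months: float = 70.0
    lod_quantile: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise CohortError("subject counts must be positive")
        if not 0 <= self.lod_quantile < 1:
            raise CohortError("lod_quantile must lie in [0, 1)")
        for e in self.effects:
            if e.tau <= 0:
                raise CohortError(f"marker {e.name}: tau must be positive")

    def null(self) -> "SimulationConfig":
        """Same cohort structure, no marker effects, all covariate ORs 1."""
        return replace(
            self,
            effects=tuple(MarkerEffect(e.name, 0.0, e.tau) for e in self.effects),
            age_case_shift=0.0,
            bmi_case_shift=0.0,
            hrt_or=1.0,
            ocp_or=1.0,
            diabetes_or=1.0,
        )


def _case_prob(p_control: float, odds_ratio: float) -> float:
    odds = odds_ratio * p_control / (1.0 - p_control)
    return odds / (1.0 + odds)


def _marker_names(cfg: SimulationConfig) -> list[str]:
    names = [e.name for e in cfg.effects]
    i = 1
    while len(names) < cfg.n_markers:
        cand = f"M{i:03d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names[: cfg.n_markers]


def _draw_log_markers(rng, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Equicorrelated Gaussian log-concentrations, one-factor construction."""
    p = cfg.n_markers
    rho = cfg.marker_corr
    z_common = rng.standard_normal((n, 1))
    z_idio = rng.standard_normal((n, p))
    z = np.sqrt(rho) * z_common + np.sqrt(1.0 - rho) * z_idio
    return cfg.marker_sigma * z


def _covariates(rng, n: int, is_case: bool, cfg: SimulationConfig) -> dict:
    age_mu = cfg.age_control_mean + (cfg.age_case_shift if is_case else 0.0)
    bmi_mu = cfg.bmi_control_mean + (cfg.bmi_case_shift if is_case else 0.0)
    age = np.clip(rng.normal(age_mu, cfg.age_sd, n), 50.0, 77.0)
    bmi = np.clip(rng.normal(bmi_mu, cfg.bmi_sd, n), 17.5, 44.5)
    out = {"age": np.round(age, 2), "bmi": np.round(bmi, 2)}
    for name, p0, orx in (
        ("hrt", cfg.hrt_control_prev, cfg.hrt_or),
        ("ocp", cfg.ocp_control_prev, cfg.ocp_or),
        ("diabetes", cfg.diabetes_control_prev, cfg.diabetes_or),
    ):
        p = _case_prob(p0, orx) if is_case else p0
        out[name] = np.where(rng.random(n) < p, "yes", "no")
    return out


def simulate_cohort(cfg: SimulationConfig = SimulationConfig()) -> Cohort:
    """Generate a pre-diagnosis discovery cohort; reproducible from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = _marker_names(cfg)
    effect_by_name = {e.name: e for e in cfg.effects}

    # case draw schedule: first draw uniform on (0, 70] months, longitudinal
    # subjects add annual earlier draws
    n_long = int(round(cfg.longitudinal_fraction * cfg.n_cases))
    long_flags = np.zeros(cfg.n_cases, dtype=bool)
    long_flags[rng.choice(cfg.n_cases, size=n_long, replace=False)] = True
    rows = []
    for i in range(cfg.n_cases):
        first = rng.uniform(np.nextafter(0.0, 1.0), cfg.max_ytd_months)
        draws = [first]
        if long_flags[i]:
            lo, hi = cfg.longitudinal_draws
            for k in range(1, int(rng.integers(lo, hi + 1))):
                draws.append(first + 12.0 * k)
        for j, ytd in enumerate(draws):
            rows.append((f"S{i:04d}", f"S{i:04d}-{j}", 1, round(ytd, 2)))
    for i in range(cfg.n_controls):
        rows.append((f"C{i:04d}", f"C{i:04d}-0", 0, np.nan))

    df = pd.DataFrame(rows, columns=["subject_id", "sample_id", "status", "ytd_months"])
    n_case_samples = int((df["status"] == 1).sum())
    n_ctrl = cfg.n_controls

    cov_case = _covariates(rng, cfg.n_cases, True, cfg)
    cov_ctrl = _covariates(rng, cfg.n_controls, False, cfg)
    # subject-level covariates replicated across a subject's draws
    subj_rows = df.loc[df["status"] == 1, "subject_id"].str[1:].astype(int).to_numpy()
    for key in ("age", "bmi", "hrt", "ocp", "diabetes"):
        vals = np.concatenate([np.asarray(cov_case[key])[subj_rows], cov_ctrl[key]])
        df[key] = vals
    df["sex"] = "female"

    logs = _draw_log_markers(rng, len(df), cfg)
    ytd_years = df["ytd_months"].to_numpy(dtype=float) / 12.0
    case_mask = (df["status"] == 1).to_numpy()
    for j, name in enumerate(names):
        eff = effect_by_name.get(name)
        if eff is not None and eff.delta != 0.0:
            logs[case_mask, j] += eff.shift(ytd_years[case_mask])
    values = np.exp(logs)

    marker_df = pd.DataFrame(np.round(values, 4), columns=names, index=df.index)
    low_mask = pd.DataFrame(False, index=df.index, columns=names)
    if cfg.lod_quantile > 0:
        ctrl_vals = marker_df.loc[~case_mask]
        lod = ctrl_vals.quantile(cfg.lod_quantile)
        for name in names:
            below = marker_df[name] < lod[name]
            low_mask[name] = below
            marker_df.loc[below, name] = np.nan

    out = pd.concat([df, marker_df], axis=1)
    assert len(out) == n_case_samples + n_ctrl
    return Cohort(out, names, low_mask)


def simulate_external_set(
    cfg: SimulationConfig = SimulationConfig(),
    drop_covariates: tuple[str, ...] = ("hrt", "ocp"),
    n_cases: int = 17,
    n_controls: int = 17,
    male_fraction: float = 14.0 / 34.0,
) -> Cohort:
    """Post-diagnosis external validation set with some covariates never collected.

    Cases are sampled at diagnosis (full marker effect); listed covariates
    (subset of hrt/ocp/bmi) are blanked to missing; sexes are mixed.
    """
    bad = set(drop_covariates) - {"hrt", "ocp", "bmi"}
    if bad:
        raise CohortError(f"cannot drop covariates: {sorted(bad)}")
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 7])
    names = _marker_names(cfg)
    effect_by_name = {e.name: e for e in cfg.effects}

    n = n_cases + n_controls
    status = np.array([1] * n_cases + [0] * n_controls)
    df = pd.DataFrame(
        {
            "subject_id": [f"X{i:04d}" for i in range(n)],
            "sample_id": [f"X{i:04d}-0" for i in range(n)],
            "status": status,
            "ytd_months": np.nan,
        }
    )
    cov_case = _covariates(rng, n_cases, True, cfg)
    cov_ctrl = _covariates(rng, n_controls, False, cfg)
    for key in ("age", "bmi", "hrt", "ocp", "diabetes"):
        df[key] = np.concatenate([np.asarray(cov_case[key]), cov_ctrl[key]])
    df["sex"] = np.where(rng.random(n) < male_fraction, "male", "female")
    # HRT/OCP do not apply to men regardless of collection
    df.loc[df["sex"] == "male", ["hrt", "ocp"]] = "no"

    logs = _draw_log_markers(rng, n, cfg)
    for j, name in enumerate(names):
        eff = effect_by_name.get(name)
        if eff is not None and eff.delta != 0.0:
            logs[status == 1, j] += eff.delta  # t = 0: full shift
    marker_df = pd.DataFrame(np.round(np.exp(logs), 4), columns=names, index=df.index)
    low_mask = pd.DataFrame(False, index=df.index, columns=names)
    if cfg.lod_quantile > 0:
        lod = marker_df.loc[status == 0].quantile(cfg.lod_quantile)
        for name in names:
            below = marker_df[name] < lod[name]
            low_mask[name] = below
            marker_df.loc[below, name] = np.nan

    for cov in drop_covariates:
        df[cov] = np.nan
    return Cohort(pd.concat([df, marker_df], axis=1), names, low_mask)
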