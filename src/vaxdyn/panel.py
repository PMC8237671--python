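"""Synthetic two-wave panel generator.

Produces respondent-level records mimicking the structure of a two-wave
vaccination-attitudes survey: 5-point Likert agreement (0-4) with getting
vaccinated under a voluntary and an enforced regime, a public-trust composite
on a 1-6.6 scale, altruism, sex, East-German origin, a pandemic-criticality
assessment, and (wave 2 only) vaccine-effectiveness belief and perceived
freedom restriction.

The generating process is a Gaussian latent index per item and wave, cut into
ordered Likert categories.  Enforced-regime support is the voluntary latent
shifted down by a within-person crowding-out term and loaded negatively on
perceived freedom restriction; a between-wave trust shock propagates into
wave-2 support through the trust loadings.  Each respondent also carries a
conformism threshold per regime (the coverage level above which they prefer
being vaccinated), coupled comonotonically across regimes so the empirical
enforced adoption curve never exceeds the voluntary one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .adoption import AdoptionCurve, make_gaussian_curve
from .errors import CalibrationError, EmptyPanelError, InvalidConfigError

__all__ = [
    "PanelConfig",
    "default_config",
    "generate_panel",
    "write_panel",
    "read_panel",
    "calibrate_to_marginals",
    "implied_adoption_curve",
]

REGIMES = ("voluntary", "enforced")
WAVES = (1, 2)
LIKERT_LEVELS = (0, 1, 2, 3, 4)

#: covariates that can carry standardized effect loadings
EFFECT_NAMES = (
    "trust",
    "altruism",
    "female",
    "east",
    "pandemic_critical",
    "effectiveness",
    "freedom",
)


def _default_effects_voluntary() -> dict[str, float]:
    return {
        "trust": 0.20,
        "altruism": 0.15,
        "female": 0.0,
        "east": -0.10,
        "pandemic_critical": 0.10,
        "effectiveness": 0.15,
        "freedom": 0.0,
    }


def _default_effects_enforced() -> dict[str, float]:
    return {
        "trust": 0.45,
        "altruism": 0.0,
        "female": -0.15,
        "east": 0.12,
        "pandemic_critical": 0.15,
        "effectiveness": 0.30,
        "freedom": -0.30,
    }


def _default_cutpoints() -> dict[str, dict[int, list[float]]]:
    # rough quantile placements; calibrate_to_marginals refines these
    return {
        "voluntary": {
            1: [-1.39, -0.99, -0.51, 0.15],
            2: [-1.39, -0.99, -0.51, 0.15],
        },
        "enforced": {
            1: [-1.57, -1.32, -0.80, -0.40],
            2: [-1.29, -0.87, -0.34, 0.16],
        },
    }


def _default_adoption() -> dict[str, dict[str, float]]:
    return {
        "voluntary": {"p0": 0.10, "p1": 1.00, "mu": 0.35, "sigma": 0.15},
        "enforced": {"p0": 0.05, "p1": 0.85, "mu": 0.50, "sigma": 0.20},
    }


@dataclass
class PanelConfig:
    """Full parameterization of the panel generator."""

    n_respondents: int = 2653
    seed: int = 0
    share_female: float = 0.47
    share_east: float = 0.20
    trust_mean: float = 4.4
    trust_sd: float = 1.0
    trust_bounds: tuple[float, float] = (1.0, 6.6)
    trust_shock_mean: float = -0.10
    trust_shock_sd: float = 0.60
    effects_voluntary: dict[str, float] = field(default_factory=_default_effects_voluntary)
    effects_enforced: dict[str, float] = field(default_factory=_default_effects_enforced)
    crowding_out_shift: float = 0.60
    individual_sd: float = 0.80
    noise_sd: float = 0.80
    cutpoints: dict[str, dict[int, list[float]]] = field(default_factory=_default_cutpoints)
    adoption: dict[str, dict[str, float]] = field(default_factory=_default_adoption)
    missing_rate: float = 0.0
    cutpoint_bounds: tuple[float, float] = (-8.0, 8.0)
    calibration_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise InvalidConfigError("n_respondents must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        for regime in REGIMES:
            for wave in WAVES:
                cps = self.cutpoints[regime][wave]
                if len(cps) != 4 or any(
                    b <= a for a, b in zip(cps, cps[1:])
                ):
                    raise InvalidConfigError(
                        f"cutpoints for {regime} wave {wave} must be 4 strictly "
                        f"ascending values, got {cps}"
                    )

    def replace(self, **kw) -> "PanelConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trust_bounds"] = list(self.trust_bounds)
        d["cutpoint_bounds"] = list(self.cutpoint_bounds)
        # YAML-friendly integer wave keys
        d["cutpoints"] = {
            r: {int(w): list(map(float, c)) for w, c in waves.items()}
            for r, waves in d["cutpoints"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        d = dict(d)
        if "trust_bounds" in d:
            d["trust_bounds"] = tuple(d["trust_bounds"])
        if "cutpoint_bounds" in d:
            d["cutpoint_bounds"] = tuple(d["cutpoint_bounds"])
        if "cutpoints" in d:
            d["cutpoints"] = {
                r: {int(w): list(map(float, c)) for w, c in waves.items()}
                for r, waves in d["cutpoints"].items()
            }
        return cls(**d)

    def adoption_curve(self, regime: str) -> AdoptionCurve:
        a = self.adoption[regime]
        return make_gaussian_curve(a["p0"], a["p1"], a["mu"], a["sigma"])


def default_config(**overrides) -> PanelConfig:
    return PanelConfig(**overrides)


# ---------------------------------------------------------------------------
# latent draws
# ---------------------------------------------------------------------------

def _draw_traits(config: PanelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = config.n_respondents
    lo, hi = config.trust_bounds
    traits = {
        "female": (rng.random(n) < config.share_female).astype(float),
        "east": (rng.random(n) < config.share_east).astype(float),
        "altruism": rng.standard_normal(n),
        "pandemic_critical": rng.standard_normal(n),
        "effectiveness": rng.standard_normal(n),
        "freedom": rng.standard_normal(n),
    }
    trust1 = np.clip(
        config.trust_mean + config.trust_sd * rng.standard_normal(n), lo, hi
    )
    shock = rng.normal(config.trust_shock_mean, config.trust_shock_sd, n)
    trust2 = np.clip(trust1 + shock, lo, hi)
    traits["trust_w1"] = trust1
    traits["trust_w2"] = trust2
    traits["propensity"] = rng.normal(0.0, config.individual_sd, n)
    return traits


def _threshold_draw(
    u: np.ndarray, params: dict[str, float]
) -> np.ndarray:
    """Inverse-CDF draw of conformism thresholds from the mixture implied by
    a gaussian-threshold adoption curve: mass p0 at 0 (always prefer), mass
    1-p1 never adopting (infinite threshold), truncated normal in between."""
    p0, p1, mu, sigma = params["p0"], params["p1"], params["mu"], params["sigma"]
    tau = np.full(u.shape, np.inf)
    tau[u < p0] = 0.0
    mid = (u >= p0) & (u < p1)
    if np.any(mid):
        a0 = norm.cdf((0.0 - mu) / sigma)
        a1 = norm.cdf((1.0 - mu) / sigma)
        q = (u[mid] - p0) / (p1 - p0)  # uniform on (0,1) given mid
        tau[mid] = mu + sigma * norm.ppf(a0 + q * (a1 - a0))
    return tau


def _standardize_trust(trust: np.ndarray, config: PanelConfig) -> np.ndarray:
    return (trust - config.trust_mean) / config.trust_sd


def _latent_index(
    config: PanelConfig,
    traits: dict[str, np.ndarray],
    regime: str,
    wave: int,
    noise: np.ndarray,
) -> np.ndarray:
    betas = (
        config.effects_voluntary if regime == "voluntary" else config.effects_enforced
    )
    z_trust = _standardize_trust(traits[f"trust_w{wave}"], config)
    x = (
        betas["trust"] * z_trust
        + betas["altruism"] * traits["altruism"]
        + betas["female"] * (traits["female"] - config.share_female)
        + betas["east"] * (traits["east"] - config.share_east)
        + betas["pandemic_critical"] * traits["pandemic_critical"]
        + betas["effectiveness"] * traits["effectiveness"]
        + betas["freedom"] * traits["freedom"]
    )
    y = x + traits["propensity"] + noise
    if regime == "enforced":
        y = y - config.crowding_out_shift
    return y


def _discretize(y: np.ndarray, cutpoints: list[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(cutpoints), y, side="left").astype(int)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

COLUMNS = [
    "respondent_id",
    "wave",
    "agree_voluntary",
    "agree_enforced",
    "trust",
    "altruism",
    "female",
    "east",
    "effectiveness",
    "freedom",
    "pandemic_critical",
    "threshold_voluntary",
    "threshold_enforced",
]


def generate_panel(config: PanelConfig) -> pd.DataFrame:
    """Generate the long-format panel: one row per respondent-wave.

    Deterministic given ``config.seed``.  Wave-1 rows have missing
    effectiveness and freedom (asked only in wave 2).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    traits = _draw_traits(config, rng)
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2, 2))  # wave x item

    u = rng.random(n)  # shared across regimes: comonotonic thresholds
    tau_v = _threshold_draw(u, config.adoption["voluntary"])
    tau_e = _threshold_draw(u, config.adoption["enforced"])

    frames = []
    for wi, wave in enumerate(WAVES):
        agree = {}
        for ri, regime in enumerate(REGIMES):
            y = _latent_index(config, traits, regime, wave, noise[:, wi, ri])
            agree[regime] = _discretize(y, config.cutpoints[regime][wave])
        df = pd.DataFrame(
            {
                "respondent_id": np.arange(n),
                "wave": wave,
                "agree_voluntary": agree["voluntary"],
                "agree_enforced": agree["enforced"],
                "trust": traits[f"trust_w{wave}"],
                "altruism": traits["altruism"],
                "female": traits["female"].astype(int),
                "east": traits["east"].astype(int),
                "effectiveness": traits["effectiveness"] if wave == 2 else np.nan,
                "freedom": traits["freedom"] if wave == 2 else np.nan,
                "pandemic_critical": traits["pandemic_critical"],
                "threshold_voluntary": tau_v,
                "threshold_enforced": tau_e,
            }
        )
        frames.append(df)
    panel = pd.concat(frames, ignore_index=True)
    panel = panel.sort_values(["respondent_id", "wave"], kind="stable").reset_index(
        drop=True
    )
    if config.missing_rate > 0.0:
        # missing-at-random on analysis covariates, to exercise list-wise exclusion
        for col in ("trust", "altruism", "effectiveness", "freedom"):
            mask = rng.random(len(panel)) < config.missing_rate
            panel.loc[mask, col] = np.nan
    return panel[COLUMNS]


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COLUMNS[:4]) - set(df.columns)
    if missing:
        raise InvalidConfigError(f"panel file lacks required columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _simulate_latents(
    config: PanelConfig, n_sim: int, seed: int
) -> dict[tuple[str, int], np.ndarray]:
    sim = config.replace(n_respondents=n_sim, seed=seed)
    rng = np.random.default_rng(seed)
    traits = _draw_traits(sim, rng)
    noise = rng.normal(0.0, sim.noise_sd, size=(n_sim, 2, 2))
    out = {}
    for wi, wave in enumerate(WAVES):
        for ri, regime in enumerate(REGIMES):
            out[(regime, wave)] = _latent_index(
                sim, traits, regime, wave, noise[:, wi, ri]
            )
    return out


def calibrate_to_marginals(
    targets: dict[str, dict[int, dict[int, float]]],
    base_config: PanelConfig | None = None,
    n_sim: int = 200_000,
    calibration_seed: int = 12345,
) -> PanelConfig:
    """Set cutpoints so simulated Likert marginals match target cumulative
    shares within 1 percentage point.

    ``targets[regime][wave][k]`` is the target share of respondents at level
    >= k, for k = 4, 3, 2, 1.  Cutpoints are placed at empirical quantiles of
    a large simulated latent sample (the fixed point of the coordinate search
    a root-finder would perform), which is deterministic given the
    calibration seed.  Cutpoints escaping the configured bounds are clipped
    and recorded in ``calibration_warnings``.
    """
    config = base_config if base_config is not None else default_config()
    latents = _simulate_latents(config, n_sim, calibration_seed)
    new_cutpoints = {
        r: {w: list(c) for w, c in waves.items()} for r, waves in config.cutpoints.items()
    }
    warnings_list: list[str] = []
    lo_b, hi_b = config.cutpoint_bounds
    for regime, waves in targets.items():
        if regime not in REGIMES:
            raise CalibrationError(f"unknown regime {regime!r} in targets")
        for wave, shares in waves.items():
            if int(wave) not in WAVES:
                raise CalibrationError(f"unknown wave {wave!r} in targets")
            shares = {int(k): float(v) for k, v in shares.items()}
            ordered = [shares[k] for k in (4, 3, 2, 1)]
            if any(not 0.0 <= s <= 1.0 for s in ordered):
                raise CalibrationError(f"target shares out of [0, 1]: {shares}")
            if any(b < a for a, b in zip(ordered, ordered[1:])):
                raise CalibrationError(
                    f"cumulative target shares must be nondecreasing from level 4 "
                    f"down to level 1: {shares}"
                )
            y = latents[(regime, int(wave))]
            cps = []
            for k in (1, 2, 3, 4):  # ascending cutpoints c1 < c2 < c3 < c4
                share_ge = shares[k]
                if share_ge >= 1.0:
                    c = lo_b
                    warnings_list.append(
                        f"{regime} wave {wave}: target share(>= {k}) = 1 pushed "
                        f"cutpoint to lower bound"
                    )
                elif share_ge <= 0.0:
                    c = hi_b
                    warnings_list.append(
                        f"{regime} wave {wave}: target share(>= {k}) = 0 pushed "
                        f"cutpoint to upper bound"
                    )
                else:
                    c = float(np.quantile(y, 1.0 - share_ge))
                    if c < lo_b or c > hi_b:
                        warnings_list.append(
                            f"{regime} wave {wave}: cutpoint for level {k} clipped "
                            f"to bounds"
                        )
                        c = float(np.clip(c, lo_b, hi_b))
                cps.append(c)
            # enforce strict ascent when targets tie or clip
            for i in range(1, 4):
                if cps[i] <= cps[i - 1]:
                    cps[i] = cps[i - 1] + 1e-9
            new_cutpoints[regime][int(wave)] = cps
    return config.replace(
        cutpoints=new_cutpoints, calibration_warnings=warnings_list
    )


# ---------------------------------------------------------------------------
# micro-to-macro link
# ---------------------------------------------------------------------------

def implied_adoption_curve(
    panel: pd.DataFrame, regime: str, f_grid
) -> np.ndarray:
    """Empirical adoption curve: for each coverage level f in ``f_grid``, the
    share of respondents whose conformism threshold is <= f under ``regime``."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    col = f"threshold_{regime}"
    rows = panel[panel["wave"] == 1] if "wave" in panel.columns else panel
    if len(rows) == 0:
        raise EmptyPanelError("panel has no rows")
    tau = rows[col].to_numpy(dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    return np.array([np.mean(tau <= f) for f in f_grid])
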