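"""Two-wave panel analysis: Likert summaries, transitions, regressions.

Operates on any long-format panel with the schema produced by
:mod:`vaxdyn.panel` (one row per respondent-wave).  The pipeline mirrors a
standard two-wave attitudes analysis: per-wave Likert means and cumulative
distributions, between-wave transition shares, standardized cross-section
OLS with and without the wave-2-only attitude items, within-person
first-difference (change) regressions, and a simple attribution of the
observed mean change to a stated trust drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    EmptyPanelError,
    InsufficientDataError,
    RankDeficiencyError,
    UnmatchedRespondentError,
)

__all__ = [
    "LikertSummary",
    "WaveSummary",
    "TransitionStats",
    "RegressionResult",
    "MODEL_A_PREDICTORS",
    "MODEL_B_PREDICTORS",
    "likert_summary",
    "transition_stats",
    "standardized_ols",
    "change_regression",
    "trust_attribution",
    "fold_increase",
]

ITEMS = ("voluntary", "enforced")
SUPPORT_LEVELS = (3, 4)  # "agreed fully or mostly"

MODEL_A_PREDICTORS = ["trust", "altruism", "female", "east", "pandemic_critical"]
MODEL_B_PREDICTORS = MODEL_A_PREDICTORS + ["effectiveness", "freedom"]

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


def _item_column(item: str) -> str:
    if item not in ITEMS:
        raise ValueError(f"unknown item {item!r}; expected one of {ITEMS}")
    return f"agree_{item}"


# ---------------------------------------------------------------------------
# Likert summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveSummary:
    mean: float
    ci: tuple[float, float]
    cumulative: dict[int, float]  # share at level >= k, k = 4, 3, 2, 1
    n: int

    @property
    def opposition_share(self) -> float:
        """Share at levels 0-1: complement of the cumulative share at >= 2."""
        return 1.0 - self.cumulative[2]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci": list(self.ci),
            "cumulative": {str(k): v for k, v in self.cumulative.items()},
            "opposition_share": self.opposition_share,
            "n": self.n,
        }


@dataclass(frozen=True)
class LikertSummary:
    item: str
    waves: dict[int, WaveSummary]

    def to_dict(self) -> dict:
        return {
            "item": self.item,
            "waves": {str(w): s.to_dict() for w, s in self.waves.items()},
        }


def likert_summary(panel: pd.DataFrame, item: str) -> LikertSummary:
    """Per-wave mean agreement with a normal-approximation 95% CI and the
    cumulative distribution share(level >= k) for k = 4, 3, 2, 1."""
    col = _item_column(item)
    waves = {}
    for wave in (1, 2):
        vals = panel.loc[panel["wave"] == wave, col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise EmptyPanelError(f"no observations for item {item!r} in wave {wave}")
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        cum = {k: float(np.mean(vals >= k)) for k in (4, 3, 2, 1)}
        waves[wave] = WaveSummary(
            mean=mean, ci=(mean - Z95 * se, mean + Z95 * se), cumulative=cum,
            n=int(vals.size),
        )
    return LikertSummary(item=item, waves=waves)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionStats:
    share_withdrew_among_prior_supporters: float
    share_became_supporters_among_prior_nonsupporters: float
    share_reduced_any: float
    share_increased_any: float
    share_level0: dict[int, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "share_withdrew_among_prior_supporters": self.share_withdrew_among_prior_supporters,
            "share_became_supporters_among_prior_nonsupporters": self.share_became_supporters_among_prior_nonsupporters,
            "share_reduced_any": self.share_reduced_any,
            "share_increased_any": self.share_increased_any,
            "share_level0": {str(k): v for k, v in self.share_level0.items()},
            "n": self.n,
        }


def _paired_waves(panel: pd.DataFrame, col: str) -> pd.DataFrame:
    """Wide respondent x wave frame for one column.

    Raises :class:`UnmatchedRespondentError` when a respondent has a row in
    only one wave.  Missing *values* (NaN within a present row) pass through
    for downstream list-wise handling.
    """
    ids1 = set(panel.loc[panel["wave"] == 1, "respondent_id"])
    ids2 = set(panel.loc[panel["wave"] == 2, "respondent_id"])
    if ids1 != ids2:
        bad = sorted(ids1 ^ ids2)[:10]
        raise UnmatchedRespondentError(f"respondents missing a wave: {bad}")
    return panel.pivot(index="respondent_id", columns="wave", values=col)


def transition_stats(panel: pd.DataFrame, item: str) -> TransitionStats:
    """Between-wave movement, with supporter = Likert level 3 or 4."""
    col = _item_column(item)
    wide = _paired_waves(panel, col).dropna()
    if len(wide) == 0:
        raise EmptyPanelError("no complete respondent pairs")
    w1, w2 = wide[1].to_numpy(), wide[2].to_numpy()
    supporters = w1 >= 3
    nonsupporters = ~supporters
    withdrew = (
        float(np.mean(w2[supporters] < 3)) if supporters.any() else float("nan")
    )
    became = (
        float(np.mean(w2[nonsupporters] >= 3)) if nonsupporters.any() else float("nan")
    )
    return TransitionStats(
        share_withdrew_among_prior_supporters=withdrew,
        share_became_supporters_among_prior_nonsupporters=became,
        share_reduced_any=float(np.mean(w2 < w1)),
        share_increased_any=float(np.mean(w2 > w1)),
        share_level0={1: float(np.mean(w1 == 0)), 2: float(np.mean(w2 == 0))},
        n=int(len(wide)),
    )


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    model_id: str
    n: int
    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    raw_coefficients: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "model_id": self.model_id,
            "n": self.n,
            "coefficients": dict(self.coefficients),
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "raw_coefficients": dict(self.raw_coefficients),
        }


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise RankDeficiencyError(name, f"predictor {name!r} has zero variance")
    return (x - x.mean()) / sd


def _fit_standardized(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    model_id: str,
    outcome_label: str,
    robust: bool = False,
) -> RegressionResult:
    data = data[[outcome] + predictors].dropna()
    if len(data) < len(predictors) + 2:
        raise InsufficientDataError(
            f"{len(data)} complete cases for {len(predictors)} predictors"
        )
    y_raw = data[outcome].to_numpy(dtype=float)
    if y_raw.std(ddof=0) == 0:
        raise RankDeficiencyError(outcome, f"outcome {outcome!r} has zero variance")
    y = _zscore(y_raw, outcome)
    cols = {p: _zscore(data[p].to_numpy(dtype=float), p) for p in predictors}
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending predictor via the smallest R diagonal of a QR
        _, r = np.linalg.qr(X)
        worst = predictors[int(np.argmin(np.abs(np.diag(r))))]
        raise RankDeficiencyError(worst)
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.OLS(y, Xc)
    fit = model.fit(cov_type="HC1") if robust else model.fit()
    ci = np.asarray(fit.conf_int())
    coefficients = {p: float(fit.params[i + 1]) for i, p in enumerate(predictors)}
    conf = {p: (float(ci[i + 1, 0]), float(ci[i + 1, 1])) for i, p in enumerate(predictors)}

    # unstandardized companions (original units), useful for attribution
    Xr = sm.add_constant(data[predictors].to_numpy(dtype=float), has_constant="add")
    fit_raw = sm.OLS(y_raw, Xr).fit()
    raw = {p: float(fit_raw.params[i + 1]) for i, p in enumerate(predictors)}

    return RegressionResult(
        outcome=outcome_label,
        model_id=model_id,
        n=int(len(data)),
        coefficients=coefficients,
        conf_int=conf,
        raw_coefficients=raw,
    )


def standardized_ols(
    panel: pd.DataFrame,
    item: str,
    wave: int,
    predictors: list[str] | None = None,
    model_id: str = "A",
    robust: bool = False,
) -> RegressionResult:
    """Cross-section OLS of Likert support on z-scored predictors.

    All variables (outcome included) are standardized to mean 0, SD 1 on the
    estimation sample after list-wise exclusion of incomplete cases.  Model
    "A" uses trust, altruism, female, east and pandemic-criticality; model
    "B" adds effectiveness and freedom (wave 2 only).
    """
    if predictors is None:
        predictors = MODEL_B_PREDICTORS if model_id == "B" else MODEL_A_PREDICTORS
    col = _item_column(item)
    rows = panel[panel["wave"] == wave]
    if len(rows) == 0:
        raise EmptyPanelError(f"no wave-{wave} rows")
    return _fit_standardized(
        rows, col, predictors, model_id, f"{item}_wave{wave}", robust=robust
    )


def change_regression(
    panel: pd.DataFrame,
    item: str,
    controls: list[str] | None = None,
    robust: bool = False,
) -> RegressionResult:
    """First-difference regression of within-person change in support on
    within-person change in trust (plus optional time-varying controls),
    removing time-invariant confounders.

    ``raw_coefficients['d_trust']`` is in Likert units per trust-scale point.
    """
    col = _item_column(item)
    support = _paired_waves(panel, col)
    trust = _paired_waves(panel, "trust")
    controls = list(controls or [])
    data = pd.DataFrame(
        {
            "d_support": support[2] - support[1],
            "d_trust": trust[2] - trust[1],
        }
    )
    for c in controls:
        cw = _paired_waves(panel, c)
        data[f"d_{c}"] = cw[2] - cw[1]
    predictors = ["d_trust"] + [f"d_{c}" for c in controls]
    return _fit_standardized(
        data, "d_support", predictors, "C", f"d_{item}", robust=robust
    )


def trust_attribution(
    beta_raw: float, trust_drop: float, observed_mean_change: float
) -> float:
    """Share of an observed mean reduction in support attributable to a
    stated drop in trust: (beta_raw * trust_drop) / |observed change|.

    ``beta_raw`` is in Likert units per trust point (from the unstandardized
    change regression); ``observed_mean_change`` is the between-wave change
    in mean support (negative for a reduction).
    """
    if observed_mean_change == 0:
        raise ZeroDivisionError("observed mean change is zero; attribution undefined")
    return (beta_raw * trust_drop) / abs(observed_mean_change)


def fold_increase(before: float, after: float) -> float:
    """Ratio of two level measurements (e.g. average daily case counts)."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return after / before


# ---------------------------------------------------------------------------
# full pipeline bundle
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def analysis_bundle(panel: pd.DataFrame, robust: bool = False) -> dict:
    """Run the whole pipeline on a panel and return a JSON-serializable dict:
    Likert summaries, transition shares, the survey-implied curve gap, and the
    three regression models (A, B cross-section; C change) for both items.

    Floats are rounded to 10 decimals so serialized bundles are byte-stable.
    """
    out: dict = {"likert": {}, "transitions": {}, "regressions": {}}
    for item in ITEMS:
        out["likert"][item] = likert_summary(panel, item).to_dict()
        out["transitions"][item] = transition_stats(panel, item).to_dict()
    support = {
        item: float(
            np.mean(
                panel.loc[panel["wave"] == 2, _item_column(item)].dropna() >= 3
            )
        )
        for item in ITEMS
    }
    from .adoption import gap_from_survey_shares

    out["gap"] = {
        "wave2_support_voluntary": support["voluntary"],
        "wave2_support_enforced": support["enforced"],
        "gap_pp": gap_from_survey_shares(support["voluntary"], support["enforced"]),
    }
    for item in ITEMS:
        out["regressions"][f"A_{item}"] = standardized_ols(
            panel, item, wave=2, model_id="A", robust=robust
        ).to_dict()
        out["regressions"][f"B_{item}"] = standardized_ols(
            panel, item, wave=2, model_id="B", robust=robust
        ).to_dict()
        out["regressions"][f"C_{item}"] = change_regression(
            panel, item, robust=robust
        ).to_dict()
    return _round_floats(out)
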