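# vaxdyn

Vaccine-acceptance dynamics under voluntary vs. enforced vaccination
policies, together with a two-wave panel survey-analysis pipeline and a
synthetic panel generator so that every stage runs without restricted data.

The package has four analysis layers plus a CLI:

- **`vaxdyn.adoption`** — regime-specific *adoption curves* `p(f)`: the share
  of the population preferring vaccination given prior coverage `f`
  (S-shaped truncated-normal-threshold family, or linear). Locates all fixed
  points of `p(f) = f`, classifies them as stable rest points or tipping
  points, and classifies a voluntary/enforced curve pair against a coverage
  target as *optimistic* (voluntary uptake alone reaches the target) or
  *pessimistic*, with the implied *enforcement burden*.
- **`vaxdyn.dynamics`** — period-by-period coverage dynamics: the willing
  are vaccinated first (ratchet `f → max(f, p(f))`); under an enforced plan,
  capacity-limited enforcement tops coverage up only when voluntary uptake
  stalls below the target, and only as far as the nearest useful tipping
  point. Tracks regret (vaccinated who prefer not to have been) and total
  enforced doses.
- **`vaxdyn.panel`** — synthetic two-wave respondent panel: 0–4 Likert
  agreement with voluntary/enforced vaccination, a 1–6.6 public-trust
  composite with a between-wave shock, altruism, sex, East-German origin,
  and wave-2-only effectiveness/freedom items; ordered-cutpoint latent
  generator with a within-person crowding-out shift, plus quantile-based
  calibration of cutpoints to target Likert marginals and an empirical
  (micro-founded) adoption curve from individual conformism thresholds.
- **`vaxdyn.analysis`** — Likert summaries with cumulative distributions,
  between-wave transition shares, standardized cross-section OLS (models A
  and B), within-person first-difference change regressions (model C), and
  the trust-attribution calculation.

## CLI

```bash
# classify a curve pair and simulate the planned policy
vaxdyn scenario examples/scenario_pessimistic.yaml -o out/ --plot

# generate a synthetic panel
vaxdyn generate examples/panel_default.yaml -o out/

# run the full analysis pipeline on a panel CSV
vaxdyn analyze out/panel.csv -o out/results/

# calibrate generator cutpoints to target cumulative Likert marginals
vaxdyn calibrate examples/panel_default.yaml examples/targets_enforced.yaml -o out/cal/
```

Every command writes a `provenance.json` (config echo + seed + version)
beside its outputs. Scenario reports are JSON, trajectories CSV
(`t, f, pref, regret, enforced_added`), panels CSV (long format, one row per
respondent-wave, empty fields for missing values).

## Library example

```python
import vaxdyn as vd

pair = vd.RegimeCurvePair(
    voluntary=vd.make_gaussian_curve(0.10, 1.00, 0.45, 0.075),
    enforced=vd.make_gaussian_curve(0.05, 0.95, 0.50, 0.08),
)
report = vd.classify_scenario(pair, target=0.8)
traj = vd.simulate(pair, vd.PolicyPlan("enforced", target=0.8), f0=0.0)
print(report.classification, report.enforcement_burden, traj.total_enforced)
```
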