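"""Registry and fitting layer for the behavioral regression battery.

Thirteen model specifications cover three families:

* GLM1.x — influences on pursue/reject decisions: current-offer value,
  lagged reward outcomes, environment richness and stochasticity, and
  choice history;
* GLM2.x — relations between decoded motivation states and behavior:
  pursue bias, behavior around state transitions, reaction time, pupil
  size, and reward availability (Ave.EV);
* GLM4.x — condition contrasts for simulated focal-stimulation data,
  with the sham condition as the reference level.

Binomial mixed models delegate to statsmodels' variational Bayes mixed
GLM and Gaussian mixed models to MixedLM; a per-subject fixed-intercept
GLM fallback (flagged in the summary) covers small synthetic datasets
where the mixed solvers are unstable.  P-values are Wald tests.
Continuous predictors are z-scored within subject before fitting; rows
with missing derived regressors are dropped listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .features import ZSCORE_COLUMNS

__all__ = [
    "ModelSpec",
    "FitSummary",
    "registry",
    "get_spec",
    "fit_model",
    "lagged_outcome_scan",
    "tus_contrasts",
    "add_state_columns",
]

_COND = "C(condition, Treatment('sham'))"

_LAG_TERMS = " + ".join(f"outcome_lag{k}" for k in range(1, 11))


@dataclass(frozen=True)
class ModelSpec:
    """One regression specification against the trial-table schema."""

    name: str
    formula: str
    family: str  # 'binomial' | 'gaussian'
    random_intercept: bool = True
    random_slope: str | None = None  # single by-subject random slope term
    groups: str = "subject_id"
    filter_query: str | None = None
    notes: str = ""

    @property
    def response(self) -> str:
        return self.formula.split("~")[0].strip()

    def required_columns(self) -> list[str]:
        import re

        bare = re.sub(r"'[^']*'", "", self.formula)  # drop quoted level names
        names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_.]*", bare))
        names -= {"C", "Treatment", "np", "log"}
        return sorted(names)


def registry() -> list[ModelSpec]:
    """All thirteen model specifications of the battery."""
    return [
        ModelSpec(
            "GLM1.1",
            f"decision ~ reward_magnitude * reward_probability + {_LAG_TERMS}",
            "binomial",
            notes="time horizon of sensitivity to past reward outcomes",
        ),
        ModelSpec(
            "GLM1.2",
            "decision ~ reward_magnitude * reward_probability + richness"
            " + stochasticity + trial_number",
            "binomial",
            notes="environment richness and stochasticity effects",
        ),
        ModelSpec(
            "GLM1.3",
            "decision ~ reward_magnitude * reward_probability + behavioral_history"
            " + richness + stochasticity + trial_number",
            "binomial",
            notes="adds previous-trial choice history",
        ),
        ModelSpec(
            "GLM2.1",
            "decision ~ reward_magnitude * reward_probability + motivation"
            " + trial_number",
            "binomial",
            random_slope="motivation",
            notes="pursue bias of the decoded high-motivation state",
        ),
        ModelSpec(
            "GLM2.2",
            "decision ~ reward_magnitude * reward_probability + after_transition"
            " + trial_number",
            "binomial",
            random_slope="after_transition",
            notes="behavior before vs after a state transition; fit per direction",
        ),
        ModelSpec(
            "GLM2.3",
            "log_rt ~ reward_magnitude + reward_probability + motivation"
            " + trial_number",
            "gaussian",
            random_intercept=False,
            random_slope="motivation",
            filter_query="decision == 1",
            notes="RT ~ motivation state; no random intercept (z-scored response)",
        ),
        ModelSpec(
            "GLM2.4",
            "pupil_decision ~ reward_magnitude + reward_probability + motivation"
            " + trial_number",
            "gaussian",
            random_intercept=False,
            random_slope="motivation",
            notes="decision-phase pupil ~ motivation state",
        ),
        ModelSpec(
            "GLM2.5",
            "motivation ~ ev + ave_ev + trial_number",
            "binomial",
            random_slope="ave_ev",
            notes="reward availability predicts motivation state",
        ),
        ModelSpec(
            "GLM4.1",
            f"decision ~ reward_magnitude * reward_probability + richness"
            f" + stochasticity + {_COND} + richness:{_COND} + trial_number",
            "binomial",
            notes="stimulation x environment-richness interaction",
        ),
        ModelSpec(
            "GLM4.2",
            f"decision ~ reward_magnitude * reward_probability + behavioral_history"
            f" + {_COND} + behavioral_history:{_COND} + trial_number",
            "binomial",
            notes="stimulation x choice-history interaction",
        ),
        ModelSpec(
            "GLM4.3",
            f"state_transition ~ reward_magnitude * reward_probability + {_COND}"
            " + trial_number",
            "binomial",
            notes="stimulation effect on state-transition frequency",
        ),
        ModelSpec(
            "GLM4.4",
            f"state_decrease ~ reward_magnitude * reward_probability + {_COND}"
            " + trial_number",
            "binomial",
            notes="stimulation effect on high-to-low transitions",
        ),
        ModelSpec(
            "GLM4.5",
            f"motivation ~ ev + ave_ev + {_COND} + ave_ev:{_COND} + trial_number",
            "binomial",
            notes="stimulation x reward-availability interaction; supports "
            "Ave.EV mean-split via filter_query",
        ),
    ]


_REGISTRY = {s.name: s for s in registry()}


def get_spec(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(_REGISTRY)}")


@dataclass
class FitSummary:
    """Per-term estimates with fit metadata."""

    model: str
    params: pd.DataFrame  # columns: term, estimate, se, z, p
    n_obs: int
    method: str  # 'mixed' or 'fixed'
    converged: bool
    notes: str = ""

    def term(self, name_contains: str) -> pd.Series:
        hit = self.params[self.params["term"].str.contains(name_contains, regex=False)]
        if hit.empty:
            raise KeyError(f"no term matching {name_contains!r} in {self.model}")
        return hit.iloc[0]


def _prepare(spec: ModelSpec, table: pd.DataFrame, zscore: bool) -> pd.DataFrame:
    data = table.copy()
    if spec.filter_query:
        data = data.query(spec.filter_query)
    needed = [c for c in spec.required_columns() if c in data.columns]
    data = data.dropna(subset=needed)
    if zscore:
        cols = set(ZSCORE_COLUMNS) | {"log_rt", "pupil_decision", "pupil_iti"}
        for col in cols & set(data.columns):
            if col == spec.response and spec.family == "binomial":
                continue
            g = data.groupby(spec.groups)[col]
            sd = g.transform("std").replace(0.0, np.nan)
            data[col] = (data[col] - g.transform("mean")) / sd
        data = data.dropna(subset=[c for c in cols & set(needed)])
    missing = [c for c in spec.required_columns() if c not in data.columns]
    if missing:
        raise ValueError(f"{spec.name}: trial table missing columns {missing}")
    if len(data) < 20:
        raise ValueError(f"{spec.name}: only {len(data)} usable rows")
    resp = data[spec.response]
    if resp.nunique() < 2 and spec.family == "binomial":
        raise ValueError(f"{spec.name}: response has no variation")
    return data


def _wald(params: pd.Series, se: pd.Series) -> pd.DataFrame:
    z = params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"term": params.index, "estimate": params.values, "se": se.values,
         "z": z.values, "p": p}
    ).reset_index(drop=True)


def _fit_fixed(spec: ModelSpec, data: pd.DataFrame) -> FitSummary:
    formula = spec.formula
    multi_subject = data[spec.groups].nunique() > 1
    if spec.random_intercept and multi_subject:
        formula = formula + f" + C({spec.groups})"
    fam = sm.families.Binomial() if spec.family == "binomial" else sm.families.Gaussian()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.glm(formula, data=data, family=fam).fit()
    params = _wald(res.params, res.bse)
    params = params[~params["term"].str.startswith(f"C({spec.groups})")]
    return FitSummary(spec.name, params.reset_index(drop=True), int(res.nobs),
                      "fixed", bool(res.converged),
                      notes="per-subject fixed intercepts" if multi_subject else "")


def _fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitSummary:
    if spec.family == "gaussian":
        re_formula = (
            ("1" if spec.random_intercept else "0")
            + (f" + {spec.random_slope}" if spec.random_slope else "")
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(spec.formula, data=data, groups=data[spec.groups],
                              re_formula=re_formula).fit()
        fe = res.fe_params
        se = res.bse.loc[fe.index]
        return FitSummary(spec.name, _wald(fe, se), int(res.nobs), "mixed",
                          bool(res.converged))
    vc = {}
    if spec.random_intercept:
        vc["subj"] = f"0 + C({spec.groups})"
    if spec.random_slope:
        vc["slope"] = f"0 + C({spec.groups}):{spec.random_slope}"
    if not vc:
        return _fit_fixed(spec, data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.BinomialBayesMixedGLM.from_formula(spec.formula, vc, data)
        res = model.fit_vb()
    fe = pd.Series(res.fe_mean, index=model.fep_names)
    se = pd.Series(res.fe_sd, index=fe.index)
    return FitSummary(spec.name, _wald(fe, se), len(data), "mixed", True,
                      notes="variational Bayes posterior mean/sd")


def fit_model(
    spec: ModelSpec | str,
    trial_table: pd.DataFrame,
    method: str = "auto",
    zscore: bool = True,
) -> FitSummary:
    """Fit one registry model to a trial table.

    ``method``: 'mixed' (random effects), 'fixed' (per-subject fixed
    intercepts), or 'auto' (mixed with fixed fallback, flagged in notes).
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    data = _prepare(spec, trial_table, zscore)
    single = data[spec.groups].nunique() == 1
    if method == "fixed" or (method == "auto" and single):
        return _fit_fixed(spec, data)
    if method == "mixed":
        return _fit_mixed(spec, data)
    try:
        out = _fit_mixed(spec, data)
        if not out.converged or not np.isfinite(out.params["se"]).all():
            raise RuntimeError("mixed fit did not converge")
        return out
    except Exception as exc:  # pragma: no cover - solver-dependent
        out = _fit_fixed(spec, data)
        out.notes = f"mixed solver failed ({exc}); fixed-intercept fallback"
        return out


def lagged_outcome_scan(
    trial_table: pd.DataFrame,
    max_lag: int = 10,
    method: str = "fixed",
    zscore: bool = True,
) -> pd.DataFrame:
    """Iterative series of decision GLMs, one per outcome lag: refit the
    lagged-outcome model giving lag k the by-subject random slope (mixed
    method) and report that lag's estimate, SE and p."""
    base = get_spec("GLM1.1")
    rows = []
    for k in range(1, max_lag + 1):
        terms = " + ".join(f"outcome_lag{j}" for j in range(1, max_lag + 1))
        spec = ModelSpec(
            f"GLM1.1-lag{k}",
            f"decision ~ reward_magnitude * reward_probability + {terms}",
            "binomial",
            random_intercept=base.random_intercept,
            random_slope=f"outcome_lag{k}" if method != "fixed" else None,
        )
        fit = fit_model(spec, trial_table, method=method, zscore=zscore)
        row = fit.term(f"outcome_lag{k}")
        rows.append({"lag": k, "estimate": row["estimate"], "se": row["se"],
                     "p": row["p"], "method": fit.method})
    return pd.DataFrame(rows)


def tus_contrasts(
    trial_table: pd.DataFrame,
    model: str = "GLM4.3",
    target: str = "DRN",
    controls: tuple = ("sham", "VTA", "STS"),
    method: str = "auto",
) -> pd.DataFrame:
    """Pairwise condition-subset fits of a GLM4.x model: the target
    condition against each control, with the control as reference level."""
    if "condition" not in trial_table.columns:
        raise ValueError("trial table has no condition column")
    levels = set(trial_table["condition"].unique())
    missing = {target, *controls} - levels
    if missing:
        raise ValueError(f"missing condition levels: {sorted(missing)}")
    base = get_spec(model)
    rows = []
    for ref in controls:
        sub = trial_table[trial_table["condition"].isin([target, ref])]
        spec = ModelSpec(
            f"{model}[{target} vs {ref}]",
            base.formula.replace("'sham'", f"'{ref}'"),
            base.family,
            random_intercept=base.random_intercept,
            random_slope=base.random_slope,
            filter_query=base.filter_query,
        )
        fit = fit_model(spec, sub, method=method)
        cond_rows = fit.params[fit.params["term"].str.contains(f"T.{target}", regex=False)]
        for _, r in cond_rows.iterrows():
            rows.append({"contrast": f"{target} vs {ref}", "term": r["term"],
                         "estimate": r["estimate"], "se": r["se"], "p": r["p"],
                         "method": fit.method})
    return pd.DataFrame(rows)


def add_state_columns(trial_table: pd.DataFrame, model) -> pd.DataFrame:
    """Decode states per session with a fitted GLM-HMM and add motivation
    (1 = high), state_transition, state_decrease, and per-direction
    before/after-transition columns used by GLM2.2."""
    from .glmhmm import build_design, decode_transitions

    X, y, sess = build_design(trial_table)
    z = model.decode(X, y, sess)
    out = trial_table.copy()
    out["motivation"] = (z == 0).astype(int)
    trans = np.zeros(len(out))
    decrease = np.zeros(len(out))
    after_h2l = np.full(len(out), np.nan)
    after_l2h = np.full(len(out), np.nan)
    pos = 0
    for sid in pd.unique(sess):
        m = sess == sid
        path = decode_transitions(z[m])
        tr = np.zeros(m.sum())
        tr[path.transitions] = 1
        trans[pos: pos + m.sum()] = tr
        dec = np.zeros(m.sum())
        for t, d in zip(path.transitions, path.directions):
            if d == "high_to_low":
                dec[t] = 1
        decrease[pos: pos + m.sum()] = dec
        for t, d in zip(path.transitions, path.directions):
            col = after_h2l if d == "high_to_low" else after_l2h
            lo = max(0, t - 5)
            col[pos + lo: pos + t] = 0.0  # five trials before the transition
            hi = min(m.sum(), t + 5)
            col[pos + t: pos + hi] = 1.0  # transition trial and aftermath
        pos += m.sum()
    out["state_transition"] = trans.astype(int)
    out["state_decrease"] = decrease.astype(int)
    out["after_transition_h2l"] = after_h2l
    out["after_transition_l2h"] = after_l2h
    return out
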