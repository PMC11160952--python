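"""Cohort-level statistics for paired-eye microvascular metrics.

Three analyses, mirroring a conventional ophthalmic reading-center workflow:

* Kruskal-Wallis tests comparing per-patient asymmetry measures across
  DR stages.
* Wilcoxon signed-rank tests for paired within-patient comparisons (e.g.
  asymmetry index in the inner vs outer ETDRS ring).
* Linear mixed models per response metric: fixed effects DR stage
  (reference "no_dr"), side (reference "right"), age, HbA1c, sex, and the
  stage x side interaction; random intercept per patient; REML estimation;
  Wald 95% CIs.  F-tests are computed for the stage and interaction terms;
  when the stage F-test rejects at alpha, per-stage contrasts against
  "no_dr" are reported, and when the interaction rejects, left-vs-right
  contrasts are reported within each stage.  No multiplicity correction is
  applied, so all p-values are descriptive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .synthetic import STAGES

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str


def kruskal_wallis(groups: Sequence[np.ndarray] | Mapping[str, np.ndarray]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test across >=2 groups.

    If every observation is identical the tie correction degenerates (0/0);
    by convention H = 0 and p = 1 are reported — no rank variation carries
    no evidence against the null.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs >=2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    ns = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return RankTestResult(0.0, 1.0, ns, "kruskal_wallis")
    stat, p = stats.kruskal(*arrays)
    return RankTestResult(float(stat), float(p), ns, "kruskal_wallis")


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Accepts paired samples ``(x, y)`` or precomputed differences ``x``.
    Zero differences are dropped; |differences| are ranked with average
    ranks for ties.  The exact null distribution is used for n <= 25,
    otherwise the normal approximation with continuity correction.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n <= EXACT_WILCOXON_MAX_N and not _has_tied_magnitudes(d):
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return RankTestResult(float(res.statistic), float(res.pvalue), (n,),
                          "wilcoxon_signed_rank")


def _has_tied_magnitudes(d: np.ndarray) -> bool:
    mags = np.abs(d)
    return np.unique(mags).size < mags.size


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed/random structure of the intereye mixed model.

    Response ~ stage + side + age + hba1c + sex + stage:side with a random
    intercept per patient.  Reference levels are fixed: stage "no_dr", side
    "right", sex "female" (sex coded 0 = female, 1 = male).
    """

    response: str = "response"
    alpha: float = 0.05
    stages: tuple[str, ...] = STAGES


@dataclass(frozen=True)
class CohortModelResult:
    """REML fit of one response metric, with everything contrasts need."""

    response: str
    n_obs: int
    n_patients: int
    n_dropped: int
    param_names: tuple[str, ...]
    estimates: np.ndarray
    cov: np.ndarray                     # fixed-effects covariance
    df_den: float
    fixed_effects: dict                 # term -> {estimate, ci, p_value}
    stage_f: dict                       # {statistic, p_value, df_num, df_den}
    interaction_f: dict
    variance_patient: float
    variance_residual: float
    spec: MixedModelSpec = field(default_factory=MixedModelSpec)

    def contrast(self, weights: Mapping[str, float]) -> dict:
        """Estimate, Wald 95% CI and p-value of a linear combination of
        fixed effects given as {param_name: weight}."""
        L = np.zeros(len(self.param_names))
        for name, w in weights.items():
            L[self.param_names.index(name)] = w
        est = float(L @ self.estimates)
        se = float(np.sqrt(L @ self.cov @ L))
        tcrit = stats.t.ppf(0.975, self.df_den)
        p = 2.0 * stats.t.sf(abs(est / se), self.df_den) if se > 0 else np.nan
        return {"estimate": est, "ci": [est - tcrit * se, est + tcrit * se],
                "p_value": float(p), "se": se}


def _design_matrix(df: pd.DataFrame, spec: MixedModelSpec):
    """Treatment-coded design: intercept, stage (vs no_dr), side (vs right),
    age, hba1c, sex (vs female), stage x side."""
    stages = list(spec.stages)
    non_ref = stages[1:]
    left = (df["side"] == "left").astype(float).to_numpy()
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for s in non_ref:
        cols[f"stage[{s}]"] = (df["stage"] == s).astype(float).to_numpy()
    cols["side[left]"] = left
    cols["age"] = df["age"].astype(float).to_numpy()
    cols["hba1c"] = df["hba1c"].astype(float).to_numpy()
    sex = df["sex"]
    if sex.dtype == object:
        cols["sex[male]"] = (sex == "male").astype(float).to_numpy()
    else:
        cols["sex[male]"] = sex.astype(float).to_numpy()
    for s in non_ref:
        cols[f"stage[{s}]:side[left]"] = cols[f"stage[{s}]"] * left
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    for j in range(X.shape[1] - 1, -1, -1):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            raise ValueError(
                f"singular design matrix: term {names[j]!r} is collinear "
                f"(e.g. a constant or confounded factor level)")
    raise ValueError("singular design matrix")


def fit_intereye_model(cohort: pd.DataFrame,
                       spec: MixedModelSpec | None = None) -> CohortModelResult:
    """REML linear mixed model of one metric on the per-eye cohort table.

    ``cohort`` needs columns ``patient_id, side, stage, age, sex, hba1c``
    and the response column named by ``spec.response``.  Rows with missing
    covariates or response are dropped with a log entry.  Requires >=2
    patients per stage with both eyes.
    """
    if spec is None:
        spec = MixedModelSpec()
    needed = ["patient_id", "side", "stage", "age", "sex", "hba1c", spec.response]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns {missing_cols}")
    df = cohort[needed].copy()
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("dropped %d rows with missing covariates/response", n_dropped)

    both = df.groupby(["stage", "patient_id"])["side"].nunique()
    per_stage = (both >= 2).groupby("stage").sum()
    thin = [s for s in spec.stages if per_stage.get(s, 0) < 2]
    if thin:
        raise ValueError(f"need >=2 complete patients per stage; too few in {thin}")

    y = df[spec.response].astype(float).to_numpy()
    X, names = _design_matrix(df, spec)
    _check_full_rank(X, names)
    groups = df["patient_id"].to_numpy()

    with warnings.catch_warnings():
        # boundary fits (zero patient variance) are legitimate here
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, pd.DataFrame(X, columns=names), groups=groups)
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            # boundary fits (patient variance ~ 0) can break gradient-based
            # optimizers; Powell is derivative-free and handles them
            fit = model.fit(reml=True, method="powell")

    k = len(names)
    beta = np.asarray(fit.fe_params, dtype=float)
    cov = np.asarray(fit.cov_params())[:k, :k]
    df_den = float(len(df) - k)

    tcrit = stats.t.ppf(0.975, df_den)
    fixed = {}
    for j, name in enumerate(names):
        se = float(np.sqrt(cov[j, j]))
        est = float(beta[j])
        p = 2.0 * stats.t.sf(abs(est / se), df_den) if se > 0 else np.nan
        fixed[name] = {"estimate": est, "ci": [est - tcrit * se, est + tcrit * se],
                       "p_value": float(p), "se": se}

    stage_terms = [f"stage[{s}]" for s in spec.stages[1:]]
    inter_terms = [f"stage[{s}]:side[left]" for s in spec.stages[1:]]
    stage_f = _wald_f(beta, cov, names, stage_terms, df_den)
    inter_f = _wald_f(beta, cov, names, inter_terms, df_den)

    return CohortModelResult(
        response=spec.response, n_obs=len(df),
        n_patients=df["patient_id"].nunique(), n_dropped=n_dropped,
        param_names=tuple(names), estimates=beta, cov=cov, df_den=df_den,
        fixed_effects=fixed, stage_f=stage_f, interaction_f=inter_f,
        variance_patient=float(np.asarray(fit.cov_re)[0, 0]),
        variance_residual=float(fit.scale), spec=spec)


def _wald_f(beta, cov, names, terms, df_den) -> dict:
    idx = [names.index(t) for t in terms]
    q = len(idx)
    b = beta[idx]
    V = cov[np.ix_(idx, idx)]
    f_stat = float(b @ np.linalg.solve(V, b)) / q
    p = float(stats.f.sf(f_stat, q, df_den))
    return {"statistic": f_stat, "p_value": p, "df_num": q, "df_den": df_den}


def branch_and_contrast(result: CohortModelResult) -> dict:
    """Apply the branching logic and assemble the final per-metric report.

    * Stage F-test p < alpha: report each stage-vs-"no_dr" contrast.  When
      the interaction is also significant the stage contrasts are reported
      per eye (right: stage main effect; left: main effect + interaction);
      otherwise they are averaged over the two eyes.
    * Interaction F-test p < alpha: report the left-vs-right contrast within
      each stage; otherwise only the single side main effect.

    p-values are descriptive (no multiplicity correction).
    """
    spec = result.spec
    alpha = spec.alpha
    report: dict = {
        "response": result.response,
        "n_obs": result.n_obs,
        "n_patients": result.n_patients,
        "n_dropped_missing": result.n_dropped,
        "alpha": alpha,
        "fixed_effects": result.fixed_effects,
        "stage_f_test": result.stage_f,
        "interaction_f_test": result.interaction_f,
        "variance_components": {"patient": result.variance_patient,
                                "residual": result.variance_residual},
    }

    interaction_significant = result.interaction_f["p_value"] < alpha

    if interaction_significant:
        side_by_stage = {}
        for s in spec.stages:
            weights = {"side[left]": 1.0}
            if s != spec.stages[0]:
                weights[f"stage[{s}]:side[left]"] = 1.0
            side_by_stage[s] = result.contrast(weights)
        report["side_by_stage"] = side_by_stage
    else:
        report["side_effect"] = result.fixed_effects["side[left]"]

    if result.stage_f["p_value"] < alpha:
        if interaction_significant:
            contrasts = {"right": {}, "left": {}}
            for s in spec.stages[1:]:
                contrasts["right"][s] = result.contrast({f"stage[{s}]": 1.0})
                contrasts["left"][s] = result.contrast(
                    {f"stage[{s}]": 1.0, f"stage[{s}]:side[left]": 1.0})
        else:
            contrasts = {}
            for s in spec.stages[1:]:
                contrasts[s] = result.contrast(
                    {f"stage[{s}]": 1.0, f"stage[{s}]:side[left]": 0.5})
        report["stage_contrasts_vs_no_dr"] = contrasts

    return report


def stage_summary(pairs: pd.DataFrame, stages: Sequence[str] = STAGES) -> pd.DataFrame:
    """Median (Q1; Q3) of asymmetry index and delta_abs per stage and metric.

    Quartiles use linear interpolation.  Returns a tidy frame with one row
    per (metric, stage, measure).
    """
    rows = []
    for (metric, stage), grp in pairs.groupby(["metric", "stage"]):
        for measure in ("delta_abs", "asymmetry_index"):
            vals = grp[measure].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((metric, stage, measure, med, q1, q3, len(vals)))
    out = pd.DataFrame(rows, columns=["metric", "stage", "measure",
                                      "median", "q1", "q3", "n"])
    order = {s: i for i, s in enumerate(stages)}
    return out.sort_values(["metric", "measure", "stage"],
                           key=lambda c: c.map(order) if c.name == "stage" else c
                           ).reset_index(drop=True)
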