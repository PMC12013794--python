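"""Statistical summaries: effect sizes, mixed models, and report tables.

Metric tables are analysed the way the field does: linear mixed models with
fixed effects for the experimental factors (muscle, plateau, contraction
type, muscle length), a random intercept per participant and a centered
trial-number covariate; factor significance via likelihood-ratio tests of
maximum-likelihood fits; estimated marginal means with 95% CIs and
Tukey-adjusted pairwise contrasts; Cohen's d (pooled SD) for group
differences.  Model fitting is delegated to statsmodels MixedLM -- no
bespoke estimation is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
import statsmodels.formula.api as smf


def cohens_d(x, y):
    """Pooled-SD standardized mean difference (mean x - mean y) / s_pooled.

    Returns None (undefined) when the pooled SD is zero.  Each sample needs
    at least two observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) \
        / (n1 + n2 - 2)
    if s2 <= 0:
        return None
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def cohens_d_model(diff: float, sigma: float) -> float:
    """Model-based effect size: a fitted contrast scaled by a model sigma.

    Distinct from the pooled-sample ``cohens_d``; use when the contrast comes
    from a mixed model rather than two raw samples.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return diff / sigma


@dataclass
class MixedModelResult:
    """Fitted mixed model with LR tests, marginal means and contrasts."""

    fit: object
    formula: str
    lr_tests: pd.DataFrame
    emmeans: dict
    pairwise: dict
    warnings: list = field(default_factory=list)


def _fit_ml(formula, table, groups):
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, table, groups=table[groups])
        res = None
        err = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError as e:  # boundary variance component
                err = e
        if res is None:
            raise RuntimeError(f"mixed-model fit failed: {err}")
    msgs = [str(w.message) for w in caught
            if "converge" in str(w.message).lower()
            or "singular" in str(w.message).lower()
            or "boundary" in str(w.message).lower()]
    return res, msgs


def fit_mixed_model(table: pd.DataFrame, response: str, factors,
                    random: str = "participant", covariate: str | None = "trial",
                    interaction: bool = True) -> MixedModelResult:
    """Fit the package's standard mixed model to a long-format metric table.

    Fixed effects: the listed ``factors`` (categorical, with their full
    interaction when ``interaction``), plus a centered numeric ``covariate``
    (pass None to omit).  Random effect: intercept per ``random`` group.
    Per-factor likelihood-ratio tests compare ML fits of the full model
    against the model without that factor (including its interactions).
    Estimated marginal means and Tukey-adjusted pairwise contrasts are
    computed per factor from the fixed-effect covariance.  Singular or
    non-converged fits are reported in ``warnings``, never silently dropped.
    """
    factors = list(factors)
    table = table.copy()
    if table[random].nunique() < 2:
        raise ValueError("need at least 2 levels of the random grouping "
                         f"factor {random!r}")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} needs at least 2 levels")

    terms = [f"C({f})" for f in factors]
    fixed = " * ".join(terms) if interaction and len(terms) > 1 \
        else " + ".join(terms)
    if covariate is not None:
        table["_cov_c"] = table[covariate] - table[covariate].mean()
        fixed = f"{fixed} + _cov_c"
    formula = f"{response} ~ {fixed}"

    full, warn_msgs = _fit_ml(formula, table, random)

    lr_rows = []
    for f in factors:
        kept = [t for t in terms if t != f"C({f})"]
        red_fixed = " + ".join(kept) if kept else "1"
        if covariate is not None:
            red_fixed += " + _cov_c"
        red, msgs = _fit_ml(f"{response} ~ {red_fixed}", table, random)
        warn_msgs += msgs
        chi2 = 2.0 * (full.llf - red.llf)
        df = int(full.df_modelwc - red.df_modelwc)
        lr_rows.append({"factor": f, "chi2": max(chi2, 0.0), "df": df,
                        "p": stats.chi2.sf(max(chi2, 0.0), max(df, 1))})
    lr_tests = pd.DataFrame(lr_rows)

    emm, pw = {}, {}
    design_info = full.model.data.design_info
    fe = np.asarray(full.fe_params)
    cov = np.asarray(full.cov_params())[: fe.size, : fe.size]
    levels = {f: sorted(table[f].unique()) for f in factors}
    ddf = max(int(table.shape[0] - fe.size), 2)
    for f in factors:
        others = [g for g in factors if g != f]
        rows = []
        lvecs = {}
        for lev in levels[f]:
            grid = []
            for combo in product(*[levels[g] for g in others]) or [()]:
                rec = {f: lev}
                rec.update(dict(zip(others, combo)))
                if covariate is not None:
                    rec["_cov_c"] = 0.0
                grid.append(rec)
            gdf = pd.DataFrame(grid)
            X = np.asarray(build_design_matrices([design_info], gdf)[0])
            L = X.mean(axis=0)
            lvecs[lev] = L
            mean = float(L @ fe)
            se = float(np.sqrt(L @ cov @ L))
            rows.append({"level": lev, "emmean": mean, "se": se,
                         "ci_lo": mean - 1.96 * se,
                         "ci_hi": mean + 1.96 * se})
        emm[f] = pd.DataFrame(rows)

        k = len(levels[f])
        contrasts = []
        for la, lb in combinations(levels[f], 2):
            L = lvecs[la] - lvecs[lb]
            diff = float(L @ fe)
            se = float(np.sqrt(L @ cov @ L))
            if se > 0:
                q = abs(diff) / se * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, ddf)) if k > 2 \
                    else 2.0 * float(stats.t.sf(abs(diff) / se, ddf))
            else:
                p = np.nan
            contrasts.append({"contrast": f"{la} - {lb}", "estimate": diff,
                              "se": se, "ci_lo": diff - 1.96 * se,
                              "ci_hi": diff + 1.96 * se, "p_tukey": p})
        pw[f] = pd.DataFrame(contrasts)

    return MixedModelResult(fit=full, formula=formula, lr_tests=lr_tests,
                            emmeans=emm, pairwise=pw,
                            warnings=sorted(set(warn_msgs)))


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_TRIAL_TABLES = {
    "delta_cv_by_contraction": ("delta_cv", ["contraction"]),
    "delta_cv_by_length": ("delta_cv", ["length"]),
    "cap_count_by_length": ("n_cap", ["length"]),
    "prop_sustained_by_length": ("prop_sustained", ["length"]),
}

_UNIT_TABLES = {
    "delta_f_by_length": ("mean_delta_f", ["length"]),
    "descend_dur_by_length": ("descend_dur", ["length"]),
    "brim_rate_delta_by_length": ("brim_rate_delta", ["length"]),
}


def _summary(df, value, by):
    cols = [c for c in by if c in df.columns]
    if df.empty or value not in df.columns or not cols:
        return pd.DataFrame(columns=cols + ["mean", "sem", "n"])
    g = df.dropna(subset=[value]).groupby(cols, observed=True)[value]
    out = g.agg(mean="mean", sem="sem", n="count").reset_index()
    return out


def build_report(trial_summaries: pd.DataFrame, unit_metrics: pd.DataFrame,
                 out_dir=None) -> dict:
    """Condition-level summary tables of the pipeline's metrics.

    Emits per-condition means/SEMs for the change in torque CV, cap counts
    and sustained proportions (trial level), and Delta-F, descending duration
    and brim rate changes (unit level).  Empty inputs yield headers-only
    tables with a warning.  When ``out_dir`` is given the tables are written
    as CSV along with simple bar figures.
    """
    if trial_summaries.empty and unit_metrics.empty:
        warnings.warn("empty metric tables: emitting headers-only report",
                      stacklevel=2)
    tables = {}
    for name, (value, by) in _TRIAL_TABLES.items():
        tables[name] = _summary(trial_summaries, value, by)
    for name, (value, by) in _UNIT_TABLES.items():
        tables[name] = _summary(unit_metrics, value, by)

    if out_dir is not None:
        import pathlib

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            if df.empty:
                continue
            fig, ax = plt.subplots(figsize=(4, 3))
            labels = df[df.columns[0]].astype(str)
            ax.bar(labels, df["mean"], yerr=df["sem"].fillna(0.0))
            ax.set_title(name.replace("_", " "))
            fig.tight_layout()
            fig.savefig(out / f"{name}.png", dpi=100)
            plt.close(fig)
    return tables
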