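"""Sex-stratified survival prioritization.

Within each sex stratum, every candidate feature is dichotomized at its
median, compared by Kaplan-Meier/log-rank, and fitted in a univariate Cox
model (Efron ties).  Features are labeled favored (high expression, better
survival) or unfavored, and partitioned into male-only / female-only /
both / neither significance classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

SCREEN_COLUMNS = [
    "feature", "stratum", "n_high", "n_low", "logrank_chi2", "logrank_p",
    "beta", "hr", "hr_ci_low", "hr_ci_high", "cox_p", "flagged", "label",
]


def median_split(values, tie_to: str = "low") -> np.ndarray:
    """Label each value 'high' or 'low' at the median.

    Values strictly above the median are 'high'; values equal to the median
    go to the ``tie_to`` side (default low, so with all-equal input every
    sample is low and the feature is skipped downstream).
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    if tie_to == "low":
        return np.where(values > med, "high", "low")
    return np.where(values >= med, "high", "low")


def km_estimate(times, statuses, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns per group a (time, survival) step table starting at S(0) = 1.
    """
    times = np.asarray(times, dtype=float)
    statuses = np.asarray(statuses, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], statuses[mask])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def logrank_test(times, statuses, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    times = np.asarray(times, dtype=float)
    statuses = np.asarray(statuses, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], statuses[a], statuses[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(times, statuses, group) -> dict:
    """Univariate Cox PH fit on a binary group indicator (Efron ties).

    Returns beta, hr = exp(beta), Wald 95% CI, p, and a ``flagged`` bool set
    when the fit hits a monotone-likelihood/convergence problem (the
    estimate at the iteration stop is still reported).
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "status": np.asarray(statuses, dtype=int),
        "group": np.asarray(group, dtype=float),
    })
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="status")
        except ConvergenceError:
            # monotone likelihood: refit with a whisper of ridge to obtain
            # a finite estimate, and flag it
            flagged = True
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="status")
        if any("convergence" in str(w.message).lower() for w in caught):
            flagged = True
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    with np.errstate(over="ignore"):  # flagged monotone fits give huge SEs
        return {
            "beta": beta,
            "se": se,
            "hr": float(np.exp(beta)),
            "hr_ci_low": float(np.exp(beta - 1.959963984540054 * se)),
            "hr_ci_high": float(np.exp(beta + 1.959963984540054 * se)),
            "p": float(cph.summary.loc["group", "p"]),
            "flagged": flagged,
        }


def survival_screen(
    features,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    significance_p: str = "logrank",
    tie_to: str = "low",
) -> tuple[pd.DataFrame, dict]:
    """Median-split survival screen of ``features`` per sex stratum.

    ``expression`` is features x samples (VST or normalized scale);
    ``samples`` must carry sex, tissue, os_time, os_status.  Only tumor
    samples with observed follow-up enter.  Returns the per feature x
    stratum call table and a cross-sex partition summary
    (male_only/female_only/both/neither over features significant at
    ``alpha`` by the chosen p-value, log-rank by default).
    """
    if significance_p not in ("logrank", "cox"):
        raise ValueError("significance_p must be 'logrank' or 'cox'")
    tumor = samples[(samples["tissue"] == "tumor")
                    & samples["os_time"].notna()
                    & samples["os_status"].notna()]
    rows = []
    sig: dict[str, set] = {"male": set(), "female": set()}
    tested: set = set()
    for sex in ("male", "female"):
        stratum = tumor[tumor["sex"] == sex]
        ids = [s for s in stratum.index if s in expression.columns]
        if len(ids) < 4:
            warnings.warn(f"{sex} stratum has < 4 usable samples; skipped",
                          stacklevel=2)
            continue
        times = stratum.loc[ids, "os_time"].to_numpy(dtype=float)
        statuses = stratum.loc[ids, "os_status"].to_numpy(dtype=int)
        for feat in features:
            if feat not in expression.index:
                warnings.warn(f"feature {feat!r} absent from expression; skipped",
                              stacklevel=2)
                continue
            values = expression.loc[feat, ids].to_numpy(dtype=float)
            groups = median_split(values, tie_to=tie_to)
            n_high = int((groups == "high").sum())
            n_low = len(groups) - n_high
            if n_high == 0 or n_low == 0:
                warnings.warn(
                    f"feature {feat!r} is degenerate (single group) in the "
                    f"{sex} stratum; skipped", stacklevel=2)
                continue
            tested.add(feat)
            chi2, lr_p = logrank_test(times, statuses, groups)
            cox = cox_univariate(times, statuses, (groups == "high").astype(float))
            p_used = lr_p if significance_p == "logrank" else cox["p"]
            label = "ns"
            if p_used < alpha:
                sig[sex].add(feat)
                label = "unfavored" if cox["hr"] > 1 else "favored"
            rows.append({
                "feature": feat, "stratum": sex,
                "n_high": n_high, "n_low": n_low,
                "logrank_chi2": chi2, "logrank_p": lr_p,
                "beta": cox["beta"], "hr": cox["hr"],
                "hr_ci_low": cox["hr_ci_low"], "hr_ci_high": cox["hr_ci_high"],
                "cox_p": cox["p"], "flagged": cox["flagged"], "label": label,
            })
    calls = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    both = sig["male"] & sig["female"]
    summary = {
        "male_only": sorted(sig["male"] - both),
        "female_only": sorted(sig["female"] - both),
        "both": sorted(both),
        "neither": sorted(tested - sig["male"] - sig["female"]),
    }
    return calls, summary
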