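"""Statistical procedures of the anesthesia assay.

* Exact two-tailed sign test for paired per-fish differences, and the
  minimal-sample-size rule n = ceil(1 - log2(alpha)) that makes an
  all-concordant outcome significant.
* The split-plot linear mixed model for normalized post-treatment frequency

      Y_ijk = d0 + d1*c_i + b_j(i) + d2*t_k + d12*c_i*t_k + e_ijk

  with concentration c_i (µL/L, 0 = control) entering as a numeric
  covariate, fish-within-treatment random intercepts b_j(i) ~ N(0, s_b^2),
  and time t_k = k/2 min on a balanced grid.
* The joint 2-df concentration-effect test H0: d1 = 0 and d12 = 0,
  realized as a likelihood-ratio test between maximum-likelihood fits with
  a chi-square(2) reference.
* The sliding-window recovery-time estimator: the model is refitted on
  15-sample windows k in {q+1, ..., q+15} for q = 0, 1, ...; the recovery
  time t_r is the start of the first window whose Bonferroni-corrected
  joint test is no longer rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import binom, chi2

MIXED_MODEL_COLUMNS = ("fish", "concentration_ul_per_l", "k", "t_min", "y_normalized")


@dataclass(frozen=True)
class SignTestResult:
    n: int
    n_positive: int
    n_negative: int
    p_value: float


def sign_test_exact(differences) -> SignTestResult:
    """Exact two-tailed sign test on paired differences.

    Ties (zero differences) are dropped and n reduced.  The p-value is
    min(1, 2 * P(Bin(n, 1/2) <= min(n+, n-))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("sign test undefined: all differences are ties")
    n_pos = int(np.sum(d > 0))
    n_neg = int(d.size - n_pos)
    p = min(1.0, 2.0 * float(binom.cdf(min(n_pos, n_neg), d.size, 0.5)))
    return SignTestResult(n=int(d.size), n_positive=n_pos, n_negative=n_neg, p_value=p)


def min_n_for_sign_test(alpha: float) -> int:
    """Smallest n whose all-concordant two-tailed sign-test p is < alpha.

    n = ceil(1 - log2(alpha)); e.g. alpha = 0.01 gives n = 8.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return math.ceil(1.0 - math.log2(alpha))


def make_mixed_model_frame(records) -> pd.DataFrame:
    """Assemble the analysis frame from (fish, concentration, k, y) records.

    ``k`` indexes the balanced 30-s grid; t_k = k/2 min is derived.  A
    ``unit`` label (fish within treatment) identifies the random-intercept
    groups.
    """
    df = pd.DataFrame(records, columns=["fish", "concentration_ul_per_l", "k", "y_normalized"])
    df["t_min"] = df["k"] / 2.0
    df["unit"] = df["fish"].astype(str) + "@" + df["concentration_ul_per_l"].astype(str)
    return df


@dataclass(frozen=True)
class MixedModelFit:
    delta0: float
    delta1: float
    delta2: float
    delta12: float
    sigma2_fish: float
    sigma2_resid: float
    loglik: float
    converged: bool
    singular: bool
    reml: bool


_FULL_FORMULA = "y_normalized ~ concentration_ul_per_l * t_min"
_REDUCED_FORMULA = "y_normalized ~ t_min"


def _ols_coefs(df: pd.DataFrame):
    x = np.column_stack([
        np.ones(len(df)),
        df["concentration_ul_per_l"].to_numpy(float),
        df["t_min"].to_numpy(float),
        df["concentration_ul_per_l"].to_numpy(float) * df["t_min"].to_numpy(float),
    ])
    y = df["y_normalized"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(np.mean(resid**2))


def fit_mixed_model(df: pd.DataFrame, reml: bool = True) -> MixedModelFit:
    """REML (or ML) fit of the split-plot model with random fish intercepts.

    Requires the ``unit`` column from :func:`make_mixed_model_frame`.  A
    zero-residual (noiseless) frame degenerates the likelihood, so such
    input falls back to the closed-form least-squares solution with both
    variance components zero and the singular flag set; boundary fits are
    likewise flagged singular rather than raised.
    """
    if "unit" not in df.columns:
        raise ValueError("frame must come from make_mixed_model_frame")
    if df.groupby("unit").ngroups < 2:
        raise ValueError("need at least two fish-within-treatment units")
    beta, mse = _ols_coefs(df)
    y_var = float(np.var(df["y_normalized"].to_numpy(float)))
    if mse <= 1e-14 * max(y_var, 1.0):
        return MixedModelFit(*[float(b) for b in beta], sigma2_fish=0.0,
                             sigma2_resid=mse, loglik=np.inf, converged=True,
                             singular=True, reml=reml)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(_FULL_FORMULA, df, groups=df["unit"])
        res = model.fit(reml=reml)
    singular = any("boundary" in str(w.message).lower() for w in caught)
    fe = res.fe_params
    return MixedModelFit(
        delta0=float(fe["Intercept"]),
        delta1=float(fe["concentration_ul_per_l"]),
        delta2=float(fe["t_min"]),
        delta12=float(fe["concentration_ul_per_l:t_min"]),
        sigma2_fish=float(res.cov_re.iloc[0, 0] * res.scale),
        sigma2_resid=float(res.scale),
        loglik=float(res.llf),
        converged=bool(res.converged),
        singular=singular,
    reml=reml)


@dataclass(frozen=True)
class JointTestResult:
    statistic: float
    p_value: float
    df: int = 2


def joint_concentration_test(df: pd.DataFrame) -> JointTestResult:
    """Likelihood-ratio test of H0: delta1 = 0 and delta12 = 0 (2 df).

    Both the full and the reduced model are refitted by maximum likelihood;
    the statistic 2*(l_full - l_reduced) is referred to chi-square(2).  The
    frame must contain exactly one test concentration plus control.
    """
    levels = sorted(df["concentration_ul_per_l"].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two treatment levels, got {levels}")

    def _ml_llf(formula: str) -> float | None:
        # boundary fits (sigma_b -> 0) report converged=False but are usable;
        # a singular profile Hessian at the exact boundary aborts statsmodels,
        # which we signal with None
        try:
            res = smf.mixedlm(formula, df, groups=df["unit"]).fit(reml=False)
        except np.linalg.LinAlgError:
            return None
        return float(res.llf) if np.isfinite(res.llf) else None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            llf_full = _ml_llf(_FULL_FORMULA)
            llf_red = _ml_llf(_REDUCED_FORMULA)
            if llf_full is None or llf_red is None:
                # sigma_b = 0 limit: the model degenerates to ordinary least
                # squares; use OLS ML likelihoods for BOTH fits to keep the
                # comparison symmetric
                llf_full = float(smf.ols(_FULL_FORMULA, df).fit().llf)
                llf_red = float(smf.ols(_REDUCED_FORMULA, df).fit().llf)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise RuntimeError(f"mixed-model fit failed: {exc}") from exc
    if not (np.isfinite(llf_full) and np.isfinite(llf_red)):
        raise RuntimeError("model likelihood is not finite")
    stat = max(0.0, 2.0 * (llf_full - llf_red))
    return JointTestResult(statistic=stat, p_value=float(chi2.sf(stat, 2)))


@dataclass(frozen=True)
class RecoveryTimeResult:
    r_index: int | None
    t_r_min: float | None
    window_p_values: dict[int, float]
    alpha: float
    correction: str
    recovered: bool


def recovery_time(df: pd.DataFrame, window_len: int = 15, q_max: int = 345,
                  alpha: float = 0.01, correction: str = "sequential") -> RecoveryTimeResult:
    """Sliding-window recovery-time estimate for one concentration vs control.

    For q = 0, 1, ... the model is refitted on the window k in
    {q+1, ..., q+window_len} and the joint concentration test computed.
    With ``correction='sequential'`` the r-th tested window's raw p is
    multiplied by r (Bonferroni over the windows examined so far); with
    ``'fixed'`` every p is multiplied by the total number of windows.  The
    recovery time t_r is the start time (q+1)/2 min of the first window at
    which the corrected null is not rejected.  Non-convergent windows are
    skipped with a warning and do not enter the correction count.
    """
    if correction not in ("sequential", "fixed"):
        raise ValueError("correction must be 'sequential' or 'fixed'")
    ks = df["k"].to_numpy()
    k_hi = int(ks.max())
    if k_hi < window_len:
        raise ValueError("grid shorter than one test window")
    q_stop = min(q_max, k_hi - window_len)
    n_windows = q_stop + 1
    p_values: dict[int, float] = {}
    r = 0
    for q in range(0, q_stop + 1):
        sub = df[(df["k"] >= q + 1) & (df["k"] <= q + window_len)]
        try:
            res = joint_concentration_test(sub)
        except RuntimeError as exc:
            warnings.warn(f"window q={q} skipped: {exc}", stacklevel=2)
            continue
        r += 1
        p_values[q] = res.p_value
        factor = r if correction == "sequential" else n_windows
        if min(1.0, res.p_value * factor) >= alpha:
            return RecoveryTimeResult(r_index=r, t_r_min=(q + 1) / 2.0,
                                      window_p_values=p_values, alpha=alpha,
                                      correction=correction, recovered=True)
    return RecoveryTimeResult(r_index=None, t_r_min=None, window_p_values=p_values,
                              alpha=alpha, correction=correction, recovered=False)
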