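"""Group statistics: paired t-maps with FDR control and mixed-effects models.

Event-locked time-frequency segments are compared with their matched
normal-breathing baselines by sample-wise paired t-tests; the resulting
p-map is thresholded with Benjamini-Hochberg FDR at q = 0.01 over the whole
map jointly. Per-event scalar EEG changes (mean over the [-5, +5] s
end-locked window, all frequencies and retained channels) are then related
to covariates with linear mixed models carrying a per-infant random
intercept and slope:

    Y_n = b0 + b1 * X_n + u_{0,i(n)} + u_{1,i(n)} * X_n + e_n
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

SLEEP_STATES = ["TA", "HVS", "ASI", "LVI"]
FDR_Q = 0.01


@dataclass
class TMap:
    t: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    significant: Optional[np.ndarray] = None


def ttest_map(event_segments: np.ndarray, baseline_segments: np.ndarray) -> TMap:
    """Sample-wise paired t-test across events (axis 0).

    Both stacks have shape (n_events, ...); samples with fewer than two
    finite pairs are masked (t, p = NaN).
    """
    ev = np.asarray(event_segments, dtype=float)
    bl = np.asarray(baseline_segments, dtype=float)
    if ev.shape != bl.shape:
        raise ValueError("event and baseline stacks must have equal shape")
    diff = ev - bl
    finite = np.isfinite(diff)
    n_pairs = finite.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sp_stats.ttest_1samp(diff, 0.0, axis=0, nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    # zero-variance differences: identical pairs give t = 0, p = 1; a
    # constant nonzero offset is an exact effect (t = +/-inf, p = 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sd = np.nanstd(np.where(finite, diff, np.nan), axis=0)
        mu = np.nanmean(np.where(finite, diff, np.nan), axis=0)
    degenerate = (sd == 0) & (n_pairs >= 2)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (mu == 0), 0.0, t)
        p = np.where(degenerate & (mu == 0), 1.0, p)
        t = np.where(degenerate & (mu != 0), np.sign(mu) * np.inf, t)
        p = np.where(degenerate & (mu != 0), 0.0, p)
    bad = n_pairs < 2
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return TMap(t=t, p=p, n_pairs=n_pairs)


def fdr_mask(p_values: np.ndarray, q: float = FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up over all samples of the map jointly."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if finite.sum() == 0:
        return mask
    rej, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
    mask[finite] = rej
    return mask


def summarize_change(change_map: np.ndarray, keep_channels: Optional[np.ndarray] = None) -> float:
    """Scalar EEG change for one event: mean over time, frequency, and the
    retained channels of an end-locked change map. NaN when every channel is
    rejected (event excluded)."""
    m = np.asarray(change_map, dtype=float)
    if keep_channels is not None:
        keep = np.asarray(keep_channels, dtype=bool)
        if not keep.any():
            return np.nan
        m = m[..., keep]
    if m.size == 0 or not np.isfinite(m).any():
        return np.nan
    return float(np.nanmean(m))


@dataclass
class LMMResult:
    covariate: str
    beta0: float
    beta1: dict  # term -> estimate (single entry for scalar covariates)
    se_beta1: dict
    p_beta1: float  # joint Wald test for categorical covariates
    re_var: dict  # random-effect variance components
    n_events: int
    n_infants: int
    converged: bool
    random_structure: str  # "intercept+slope" or "intercept"
    p_method: str = "wald-z"
    fitted: object = field(default=None, repr=False)


def _fit_mixed(df: pd.DataFrame, formula: str, re_formula: str):
    last_err = None
    for methods in (["lbfgs", "powell"], ["powell"], ["cg"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, df, groups=df["infant_id"], re_formula=re_formula)
                return md.fit(reml=True, method=methods)
        except np.linalg.LinAlgError as e:  # singular RE covariance mid-iteration
            last_err = e
    raise last_err


def fit_lmm(
    df: pd.DataFrame,
    covariate: str,
    response: str = "eeg_change",
    min_infants: int = 5,
) -> LMMResult:
    """Linear mixed model of EEG change on one covariate.

    Fixed intercept + slope; per-infant random intercept + random slope
    (restricted maximum likelihood). ``sleep_state`` enters as a 4-level
    categorical (reference TA) with a random intercept only, and ``p_beta1``
    is the joint Wald test of its three contrasts. Rows with missing
    response/covariate are dropped. A singular random-slope covariance
    triggers a flagged refit with random intercept only.
    """
    d = df[[response, covariate, "infant_id"]].dropna().copy()
    n_inf = d["infant_id"].nunique()
    if n_inf < min_infants:
        raise ValueError(f"need >= {min_infants} infants, got {n_inf}")
    categorical = covariate == "sleep_state" or d[covariate].dtype == object
    if not categorical and np.var(d[covariate].to_numpy(dtype=float)) == 0:
        raise ValueError("covariate has zero variance")

    if categorical:
        formula = f"{response} ~ C({covariate}, Treatment('TA'))"
        re_formula = "~1"
        structure = "intercept"
    else:
        formula = f"{response} ~ {covariate}"
        re_formula = f"~{covariate}"
        structure = "intercept+slope"

    try:
        res = _fit_mixed(d, formula, re_formula)
        singular = (
            structure == "intercept+slope"
            and (np.any(np.diag(res.cov_re) < 1e-12) or not np.all(np.isfinite(res.bse_fe)))
        )
    except np.linalg.LinAlgError:
        if structure == "intercept":
            raise
        res, singular = None, True
    if singular:
        log.warning("singular random-effects covariance for %s: refit intercept-only", covariate)
        res = _fit_mixed(d, formula, "~1")
        structure = "intercept"

    fe = res.fe_params
    slope_terms = [t for t in fe.index if t != "Intercept"]
    beta1 = {t: float(fe[t]) for t in slope_terms}
    se = {t: float(res.bse_fe[t]) for t in slope_terms}
    if categorical:
        contrast = np.zeros((len(slope_terms), len(res.params)))
        names = list(res.params.index)
        for i, t in enumerate(slope_terms):
            contrast[i, names.index(t)] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = res.wald_test(contrast, scalar=True)
        p = float(wt.pvalue)
    else:
        p = float(res.pvalues[slope_terms[0]])

    re_var = {str(k): float(v) for k, v in zip(res.cov_re.index, np.diag(res.cov_re))}
    return LMMResult(
        covariate=covariate,
        beta0=float(fe["Intercept"]),
        beta1=beta1,
        se_beta1=se,
        p_beta1=p,
        re_var=re_var,
        n_events=len(d),
        n_infants=int(n_inf),
        converged=bool(res.converged),
        random_structure=structure,
        fitted=res,
    )


def fit_all_models(df: pd.DataFrame, covariates: Sequence[str] = (
    "hr_change", "spo2_change", "duration_s", "pma_weeks", "sleep_state",
)) -> list[LMMResult]:
    """The five association models, each fitted separately.

    For ``pma_weeks`` the response is first averaged per recording (one row
    per recording), since pause counts vary across recordings.
    """
    out = []
    for cov in covariates:
        if cov not in df.columns:
            log.warning("covariate %s absent: skipped", cov)
            continue
        d = df
        if cov == "pma_weeks":
            d = (
                df.dropna(subset=["eeg_change"])
                .groupby(["infant_id", "recording_id"], as_index=False)
                .agg(eeg_change=("eeg_change", "mean"), pma_weeks=("pma_weeks", "first"))
            )
        try:
            out.append(fit_lmm(d, cov))
        except ValueError as e:
            log.warning("model for %s not fitted: %s", cov, e)
    return out
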