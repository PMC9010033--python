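"""Longitudinal and group-difference models.

Linear mixed models with a per-patient random intercept are used for two
validation analyses: Shannon diversity over days on chemotherapy with a
coalescence x time interaction, and the shared:unique OTU ratio over time.
Estimation is REML (statsmodels ``MixedLM``); the interaction is reported
both as a Wald z test on the REML coefficient and as a likelihood-ratio
comparison of maximum-likelihood fits with and without the interaction
(the analysis-of-variance style test).  No denominator degrees-of-freedom
correction is applied: inference is large-sample.

Group comparisons are Mann-Whitney rank-sum (unpaired) or Wilcoxon
signed-rank (paired) tests with Benjamini-Hochberg FDR adjustment applied
across the explicitly supplied family of comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = ["LmmSpec", "LmmFit", "fit_lmm", "bh_adjust", "group_difference_tests"]


@dataclass
class LmmSpec:
    """Model specification for a random-intercept linear mixed model.

    ``fixed`` is a patsy right-hand-side formula (e.g. ``"day * coalesced"``
    or ``"site + timepoint"``); the random structure is always an intercept
    per ``group`` (the patient).
    """

    response: str
    fixed: str = "day * coalesced"
    group: str = "patient_id"
    reml: bool = True
    interaction_term: str | None = None


@dataclass
class LmmFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    converged: bool
    n_obs: int
    n_groups: int
    lrt_interaction_p: float | None = None
    lrt_stat: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse, "p": self.pvalues})


def _formula(spec: LmmSpec) -> str:
    return f"{spec.response} ~ {spec.fixed}"


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """REML fit of a random-intercept LMM, with an optional LRT.

    Raises on a rank-deficient fixed-effects design (naming the aliased
    columns).  If ``spec.interaction_term`` is set, the model is refit by
    maximum likelihood with and without that term and the likelihood-ratio
    p-value (1 df chi-square) is reported alongside the Wald tests.
    """
    data = data.dropna(subset=[spec.response]).copy()
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least two patients")
    model = smf.mixedlm(_formula(spec), data, groups=data[spec.group])
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        u, s, vt = np.linalg.svd(model.exog)
        aliased = [model.exog_names[i] for i in np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]]
        raise ValueError(f"singular fixed-effects design; aliased columns: {aliased}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=spec.reml)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        log.warning("mixed model did not converge; estimates are provisional")

    fe = res.fe_params.index
    fit = LmmFit(
        params=res.fe_params,
        bse=res.bse[fe],
        pvalues=res.pvalues[fe],
        group_var=float(res.cov_re.iloc[0, 0]),
        resid_var=float(res.scale),
        converged=converged,
        n_obs=int(model.nobs),
        n_groups=int(data[spec.group].nunique()),
    )

    if spec.interaction_term:
        term = spec.interaction_term
        reduced_fixed = _drop_term(spec.fixed, term)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm(_formula(spec), data, groups=data[spec.group]).fit(reml=False)
            red = smf.mixedlm(f"{spec.response} ~ {reduced_fixed}", data,
                              groups=data[spec.group]).fit(reml=False)
        lrt = 2.0 * (full.llf - red.llf)
        fit.lrt_stat = float(max(lrt, 0.0))
        fit.lrt_interaction_p = float(stats.chi2.sf(fit.lrt_stat, df=1))
    return fit


def _drop_term(fixed: str, term: str) -> str:
    """Expand ``a * b`` to main effects + interaction and drop one term."""
    expanded = fixed
    if "*" in fixed:
        parts = [p.strip() for p in fixed.split("*")]
        if len(parts) == 2:
            a, b = parts
            expanded = f"{a} + {b} + {a}:{b}"
    terms = [t.strip() for t in expanded.split("+")]
    kept = [t for t in terms if _canon(t) != _canon(term)]
    if len(kept) == len(terms):
        raise ValueError(f"term {term!r} not found in fixed effects {fixed!r}")
    return " + ".join(kept) if kept else "1"


def _canon(term: str) -> frozenset:
    return frozenset(p.strip() for p in term.split(":"))


# ---------------------------------------------------------------------------
# Rank tests with BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def group_difference_tests(comparisons: dict, paired: bool = False) -> pd.DataFrame:
    """Rank tests over an explicit family of comparisons, BH-adjusted.

    Parameters
    ----------
    comparisons
        Mapping comparison name -> (x, y) arrays.  With ``paired=True`` a
        Wilcoxon matched-pairs signed-rank test is applied (x and y equal
        length); otherwise a two-sided Mann-Whitney rank-sum test.

    The BH adjustment runs across exactly the supplied comparisons, so a
    per-taxonomy-level family is expressed by one call per level.
    """
    rows = []
    for name, (x, y) in comparisons.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if paired:
            if len(x) != len(y):
                raise ValueError(f"{name}: paired test needs equal lengths")
            diffs = x - y
            if np.all(diffs == 0):
                log.warning("%s: all paired differences are zero; p set to 1", name)
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(x, y)
        else:
            if len(x) == 0 or len(y) == 0:
                raise ValueError(f"{name}: both groups need observations")
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"comparison": name, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
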