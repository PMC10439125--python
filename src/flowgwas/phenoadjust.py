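"""Two-stage removal of extraneous trait variation.

Haematology-analyser traits carry technical variation (between-analyser
offsets, slow drift, calibration events, seasonal physiology, sample
ageing between venipuncture and analysis, day-of-week structure) and
physiological variation (age, menopause, body size, smoking, alcohol)
that is noise from the point of view of a GWAS.  The workflow here:

1. pre-transform each measured trait according to its support class
   (log for positive traits, logit for proportions);
2. stage 1: fit an additive smooth model of the transformed trait on
   the technical covariates and keep re-centred residuals (the
   "technically adjusted" trait);
3. stage 2: fit a second smooth model on baseline physiological
   covariates and keep the residuals;
4. recompute derived traits from their adjusted measured inputs;
5. robust outlier filters (median/MAD rules, and a chi-squared filter
   on leading principal-component scores within cell-type groups);
6. stratified quantile-inverse-normal transformation (by analyser, sex
   and menopausal status) to exact normal scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from . import smoothing
from .synthdata import (
    ALC_LEVELS,
    DRK_LEVELS,
    MENO_LEVELS,
    SECONDS_PER_YEAR,
    SFRQ_LEVELS,
    SMK_LEVELS,
)

logger = logging.getLogger(__name__)

#: consistency factor making the MAD estimate the SD under normality
MAD_SCALE = 1.4826


@dataclass
class TraitSpec:
    """Registry entry for one trait.

    ``support`` selects the pre-transform (``positive`` -> natural log,
    ``proportion`` -> logit after percentage rescaling, ``unbounded`` ->
    identity).  Derived traits carry a ``derivation`` expression over
    measured trait names and are recomputed, not regression-adjusted.
    """

    name: str
    support: str = "unbounded"
    kind: str = "measured"
    derivation: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.support not in ("positive", "proportion", "unbounded"):
            raise ValueError(f"unknown support class {self.support!r}")
        if self.kind not in ("measured", "derived"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "derived" and not self.derivation:
            raise ValueError(f"derived trait {self.name!r} needs a derivation expression")


def pre_transform(values: np.ndarray, support: str) -> np.ndarray:
    """Map a measured trait onto its analysis scale.

    Positive traits are natural-log transformed; proportions are logit
    transformed (percentages detected by values above 1 and divided by
    100; exact 0/1 nudged inward by half the smallest observed spacing);
    unbounded traits pass through.  Domain violations raise and name the
    offending sample index.
    """
    v = np.asarray(values, dtype=float)
    if support == "unbounded":
        return v.copy()
    if support == "positive":
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise ValueError(f"positive-support trait has non-positive value at sample {bad[0]}")
        return np.log(v)
    if support == "proportion":
        x = v / 100.0 if np.nanmax(v) > 1.0 else v.copy()
        bad = np.where((x < 0) | (x > 1))[0]
        if bad.size:
            raise ValueError(f"proportion trait outside [0,1] at sample {bad[0]}")
        distinct = np.unique(x[np.isfinite(x)])
        if ((x == 0) | (x == 1)).any():
            eps = 0.5 * np.min(np.diff(distinct)) if distinct.size > 1 else 1e-6
            logger.info("nudging exact 0/1 proportions inward by %g", eps)
            x = np.clip(x, eps, 1 - eps)
        return np.log(x / (1 - x))
    raise ValueError(f"unknown support class {support!r}")


def inverse_pre_transform(values: np.ndarray, support: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if support == "unbounded":
        return v.copy()
    if support == "positive":
        return np.exp(v)
    if support == "proportion":
        return 1.0 / (1.0 + np.exp(-v))
    raise ValueError(f"unknown support class {support!r}")


# ---------------------------------------------------------------------------
# stage-1 technical adjustment


@dataclass
class StageFit:
    residuals: np.ndarray
    fit: smoothing.AdditiveFit
    notes: list[str] = field(default_factory=list)


def fit_stage1(
    y: np.ndarray,
    cov: pd.DataFrame,
    df_uni: int = 10,
    df_biv: tuple[int, int] = (5, 6),
    min_per_level: int = 50,
) -> StageFit:
    """Technical adjustment: smooth model of trait on measurement-time
    covariates.

    The design contains a penalised smooth of seconds-since-study-start
    expanded per analyser (factor-by-smooth: analyser main effect plus
    one smooth per analyser), a cyclic smooth of seconds-since-new-year,
    a bivariate tensor-product smooth of (time of day, venipuncture
    interval) expanded over analyser x imputation-flag levels, and
    day-of-week dummies (baseline monday).  Residuals are re-centred to
    the mean of the unadjusted transformed trait.

    Levels with fewer than ``min_per_level`` observations cause the
    corresponding interaction to be coarsened (and, with a single
    analyser, dropped) with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(cov) != n:
        raise ValueError("trait and covariate lengths differ")
    notes: list[str] = []

    analyser = cov["analyser"].to_numpy().astype(str)
    levels, counts = np.unique(analyser, return_counts=True)
    terms: list[smoothing.Term] = []

    t = cov["t"].to_numpy(float)
    b_t = smoothing.bspline_basis(t, df=df_uni)
    s_t = smoothing.difference_penalty(df_uni)
    if len(levels) >= 2 and counts.min() >= min_per_level:
        terms.append(smoothing.dummy_columns(analyser, name="analyser"))
        terms.extend(smoothing.factor_by_smooth("s(t)", b_t, s_t, analyser))
    else:
        if len(levels) >= 2:
            msg = "analyser level below minimum count; dropping the smooth-by-analyser interaction"
            terms.append(smoothing.dummy_columns(analyser, name="analyser"))
        else:
            msg = "single analyser level; dropping the analyser interaction"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
        terms.append(smoothing.Term("s(t)", b_t, s_t))

    b_year = smoothing.cyclic_bspline_basis(
        cov["t_year"].to_numpy(float), period=SECONDS_PER_YEAR, df=df_uni
    )
    terms.append(smoothing.Term("c(t_year)", b_year, smoothing.cyclic_penalty(df_uni)))

    b_day = smoothing.bspline_basis(cov["t_day"].to_numpy(float), df=df_biv[0])
    b_ven = smoothing.bspline_basis(cov["t_ven"].to_numpy(float), df=df_biv[1])
    t_biv, s_biv = smoothing.tensor_basis(b_day, b_ven)
    combo = np.char.add(
        np.char.add(analyser, ":"), cov["t_ven_imputed"].to_numpy().astype(str)
    )
    c_levels, c_counts = np.unique(combo, return_counts=True)
    if len(c_levels) > 1 and c_counts.min() >= min_per_level:
        terms.extend(smoothing.factor_by_smooth("tp(t_day,t_ven)", t_biv, s_biv, combo))
        terms.append(smoothing.dummy_columns(combo, name="m:I"))
    else:
        if len(c_levels) > 1:
            notes.append("sparse (analyser, imputed) level; fitting a single bivariate smooth")
        terms.append(smoothing.Term("tp(t_day,t_ven)", t_biv, s_biv))
        terms.append(
            smoothing.Term(
                "I", cov["t_ven_imputed"].to_numpy(float).reshape(-1, 1), None, centre=True
            )
        )

    terms.append(smoothing.dummy_columns(cov["day_of_week"].to_numpy(), baseline="monday", name="dow"))

    fit = smoothing.fit_additive(y, terms)
    residuals = fit.residuals + y.mean()  # re-centre to the unadjusted mean
    return StageFit(residuals=residuals, fit=fit, notes=notes)


# ---------------------------------------------------------------------------
# stage-2 baseline adjustment

_CATEGORICAL_ENUMS = {
    "meno": set(MENO_LEVELS),
    "drk": set(DRK_LEVELS),
    "alc": set(ALC_LEVELS),
    "smk": set(SMK_LEVELS),
    "sfrq": set(SFRQ_LEVELS),
}


def _check_levels(cov: pd.DataFrame) -> None:
    for col, allowed in _CATEGORICAL_ENUMS.items():
        seen = set(cov[col].astype(str))
        extra = seen - allowed
        if extra:
            raise ValueError(f"unseen level {sorted(extra)[0]!r} in covariate {col!r}")


def _pool_sparse_meno(meno: np.ndarray, min_count: int) -> tuple[np.ndarray, list[str]]:
    """Pool menopause levels below the minimum count into the largest
    female level (documented pooling rule); 'male' is never pooled."""
    m = meno.astype(str).copy()
    notes = []
    levels, counts = np.unique(m, return_counts=True)
    female = [(lev, c) for lev, c in zip(levels, counts) if lev != "male"]
    if not female:
        return m, notes
    target = max(female, key=lambda lc: lc[1])[0]
    for lev, c in female:
        if c < min_count and lev != target:
            m[m == lev] = target
            msg = f"pooled sparse menopause level {lev!r} (n={c}) into {target!r}"
            logger.warning(msg)
            notes.append(msg)
    return m, notes


def fit_stage2(
    r1: np.ndarray,
    cov: pd.DataFrame,
    df_uni: int = 10,
    df_biv: tuple[int, int] = (5, 6),
    min_per_level: int = 50,
) -> StageFit:
    """Baseline adjustment: smooth model on physiological covariates.

    Smooth of age per menopause level, bivariate smooth of
    (log weight, log height) per menopause level, missingness-flag
    dummies, drinking/alcohol dummies, a smooth of pack-years, smoking
    dummies and trial-arm dummies (baseline M8).
    """
    r1 = np.asarray(r1, dtype=float)
    if len(cov) != len(r1):
        raise ValueError("residual and covariate lengths differ")
    _check_levels(cov)

    meno, notes = _pool_sparse_meno(cov["meno"].to_numpy(), min_per_level)
    terms: list[smoothing.Term] = [smoothing.dummy_columns(meno, name="meno")]

    b_age = smoothing.bspline_basis(cov["age"].to_numpy(float), df=df_uni)
    s_uni = smoothing.difference_penalty(df_uni)
    terms.extend(smoothing.factor_by_smooth("s(age)", b_age, s_uni, meno))

    b_w = smoothing.bspline_basis(np.log(cov["wgt"].to_numpy(float)), df=df_biv[0])
    b_h = smoothing.bspline_basis(np.log(cov["hgt"].to_numpy(float)), df=df_biv[1])
    t_biv, s_biv = smoothing.tensor_basis(b_w, b_h)
    terms.extend(smoothing.factor_by_smooth("tp(lwgt,lhgt)", t_biv, s_biv, meno))

    for flag in ("wgt_na", "hgt_na", "pckyrs_na"):
        terms.append(smoothing.Term(flag, cov[flag].to_numpy(float).reshape(-1, 1), None))

    terms.append(smoothing.dummy_columns(cov["drk"].to_numpy(), baseline="never", name="drk"))
    terms.append(smoothing.dummy_columns(cov["alc"].to_numpy(), baseline="never", name="alc"))
    b_pck = smoothing.bspline_basis(cov["pckyrs"].to_numpy(float), df=df_uni)
    terms.append(smoothing.Term("s(pckyrs)", b_pck, s_uni))
    terms.append(smoothing.dummy_columns(cov["smk"].to_numpy(), baseline="never", name="smk"))
    terms.append(smoothing.dummy_columns(cov["sfrq"].to_numpy(), baseline="never", name="sfrq"))
    terms.append(smoothing.dummy_columns(cov["arm"].to_numpy(), baseline="M8", name="arm"))

    fit = smoothing.fit_additive(r1, terms)
    return StageFit(residuals=fit.residuals + r1.mean(), fit=fit, notes=notes)


# ---------------------------------------------------------------------------
# derived traits, outlier filters, inverse-normal transform


def recompute_derived(adjusted: pd.DataFrame, specs: list[TraitSpec]) -> pd.DataFrame:
    """Evaluate derivation expressions on adjusted measured traits.

    Derived traits may reference measured traits only; a derivation
    naming another derived trait is a configuration error (this also
    rules out cycles).  Missing inputs propagate to missing outputs.
    """
    measured = {s.name for s in specs if s.kind == "measured"}
    out = {}
    for s in specs:
        if s.kind != "derived":
            continue
        tokens = {
            tok
            for tok in pd.core.computation.parsing.tokenize_string(s.derivation)
            if tok[0] == 1  # NAME tokens
        }
        names = {t[1] for t in tokens}
        bad = names - measured
        if bad:
            raise ValueError(
                f"derived trait {s.name!r} references non-measured name(s) {sorted(bad)}"
            )
        out[s.name] = adjusted.eval(s.derivation)
    return pd.DataFrame(out, index=adjusted.index)


def scaled_mad(x: np.ndarray, scale: float = MAD_SCALE) -> float:
    x = np.asarray(x, dtype=float)
    return scale * float(np.median(np.abs(x - np.median(x))))


def filter_outliers(
    raw_on_scale: np.ndarray,
    adjusted: np.ndarray,
    diff_mads: float = 3.5,
    resid_mads: float = 4.5,
    mad_scale: float = MAD_SCALE,
) -> pd.DataFrame:
    """Median/MAD outlier rules applied once, in sequence.

    Rule 1 removes points whose adjustment (raw minus adjusted, on the
    analysis scale) is more than ``diff_mads`` scaled MADs from the
    median adjustment; rule 2 then removes surviving points whose
    adjusted value is more than ``resid_mads`` scaled MADs from the
    survivors' median.  Returns a frame with ``include`` and a
    ``reason`` code ('', 'large_adjustment' or 'residual_outlier').  A
    zero MAD skips the corresponding rule with a warning.
    """
    raw = np.asarray(raw_on_scale, dtype=float)
    adj = np.asarray(adjusted, dtype=float)
    if raw.shape != adj.shape:
        raise ValueError("raw and adjusted vectors are not aligned")
    include = np.ones(len(raw), dtype=bool)
    reason = np.array([""] * len(raw), dtype=object)

    diff = raw - adj
    mad1 = scaled_mad(diff, mad_scale)
    if mad1 == 0.0:
        warnings.warn("adjustment differences have zero MAD; rule skipped", stacklevel=2)
    else:
        fire = np.abs(diff - np.median(diff)) > diff_mads * mad1
        include[fire] = False
        reason[fire] = "large_adjustment"

    surv = adj[include]
    mad2 = scaled_mad(surv, mad_scale)
    if mad2 == 0.0:
        warnings.warn("residuals have zero MAD; rule skipped", stacklevel=2)
    else:
        fire = include & (np.abs(adj - np.median(surv)) > resid_mads * mad2)
        include[fire] = False
        reason[fire] = "residual_outlier"

    return pd.DataFrame({"include": include, "reason": reason})


def filter_multivariate(group: np.ndarray, d: int, tail: float = 1e-7) -> pd.DataFrame:
    """Chi-squared filter on leading principal-component scores.

    Traits of one cell-type group are standardised and decomposed by
    principal components; each sample's sum of squared leading-``d``
    standardised scores is compared with the upper ``tail`` quantile of
    a chi-squared distribution with ``d`` degrees of freedom.
    """
    x = np.asarray(group, dtype=float)
    n, k = x.shape
    if d > k:
        raise ValueError("d exceeds the number of traits in the group")
    if n <= k:
        raise ValueError("fewer samples than traits; principal components undefined")
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    _, svals, vt = np.linalg.svd(xs, full_matrices=False)
    scores = xs @ vt.T  # n x k, columns ordered by variance
    score_sd = svals / np.sqrt(n - 1)
    z = scores[:, :d] / score_sd[:d]
    stat = np.sum(z**2, axis=1)
    threshold = chi2.isf(tail, df=d)
    return pd.DataFrame({"include": stat <= threshold, "statistic": stat})


def int_transform(
    values: np.ndarray,
    strata: pd.DataFrame | np.ndarray,
    min_stratum: int = 10,
    offset: tuple[float, float] = (3.0 / 8.0, 1.0 / 4.0),
) -> pd.DataFrame:
    """Stratified quantile-inverse-normal transform to exact normal scores.

    Within each stratum (analyser x sex x menopause in the pipeline)
    values are replaced by Phi^-1((rank - 3/8) / (n + 1/4)) with ties
    sharing the average rank.  Strata below ``min_stratum`` are excluded
    and flagged rather than transformed.
    """
    v = np.asarray(values, dtype=float)
    if isinstance(strata, pd.DataFrame):
        labels = strata.astype(str).agg(":".join, axis=1).to_numpy()
    else:
        labels = np.asarray(strata).astype(str)
    if len(labels) != len(v):
        raise ValueError("values and strata are not aligned")

    a, b = offset
    out = np.full(len(v), np.nan)
    included = np.zeros(len(v), dtype=bool)
    for lev in np.unique(labels):
        mask = labels == lev
        n = int(mask.sum())
        if n < min_stratum:
            logger.warning("stratum %r below minimum size (%d); excluded", lev, n)
            continue
        r = rankdata(v[mask], method="average")
        out[mask] = norm.ppf((r - a) / (n + b))
        included[mask] = True
    return pd.DataFrame({"value": out, "include": included, "stratum": labels})
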