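"""Alpha-granule protein classification and directional enrichment.

Platelet alpha-granules store the coagulation factors, growth factors
and chemokines that activated platelets release into plasma.  Two
analyses live here:

* classification of alpha-granule proteins from a subtractive
  mass-spectrometry comparison of grey-platelet-syndrome platelets
  (which lack alpha-granules) against healthy controls;
* the directional enrichment analysis asking whether a variant's
  negative effects on plasma protein concentrations concentrate among
  alpha-granule proteins — a 2x2 Fisher's exact test over the sign of
  the effect estimates of megakaryocyte-expressed proteins, plus a
  linear regression of effect size on the granule label adjusting for
  megakaryocyte mRNA expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import ttest_ind

DEFAULT_P_THRESH = 1e-3
DEFAULT_FPKM_THRESH = 1.0


def classify_alpha_granule(
    gps_navs: np.ndarray,
    ctrl_navs: np.ndarray,
    p_max: float = 0.05,
    sd_mult: float = 2.0,
    spread: str = "sd",
    log_offset: float = 0.0,
) -> pd.DataFrame:
    """Label proteins alpha-granule from GPS-vs-control abundances.

    ``gps_navs`` and ``ctrl_navs`` are (proteins x replicates) matrices
    of normalised abundance values.  A protein is labelled iff (a) a
    Welch two-sample t-test on the log abundances is significant at
    ``p_max``, (b) its log-ratio (mean log GPS - mean log control) lies
    more than ``sd_mult`` spreads from the median log-ratio (spread =
    ordinary SD by default; ``spread='mad'`` switches to the scaled
    MAD), and (c) it is *less* abundant in GPS platelets.  Zero
    abundances are handled by ``log_offset`` with a warning.
    """
    gps = np.asarray(gps_navs, dtype=float)
    ctrl = np.asarray(ctrl_navs, dtype=float)
    if gps.shape[0] != ctrl.shape[0]:
        raise ValueError("protein counts differ between groups")
    if gps.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least two replicates per group")
    if (gps <= 0).any() or (ctrl <= 0).any():
        if log_offset <= 0:
            raise ValueError("non-positive abundances need a positive log_offset")
        warnings.warn("non-positive abundances offset before log", stacklevel=2)
    lg = np.log(gps + log_offset)
    lc = np.log(ctrl + log_offset)

    pvals = ttest_ind(lg, lc, axis=1, equal_var=False).pvalue
    ratio = lg.mean(axis=1) - lc.mean(axis=1)
    centre = np.median(ratio)
    if spread == "sd":
        s = ratio.std(ddof=1)
    elif spread == "mad":
        s = 1.4826 * np.median(np.abs(ratio - centre))
    else:
        raise ValueError("spread must be 'sd' or 'mad'")
    label = (pvals <= p_max) & (np.abs(ratio - centre) > sd_mult * s) & (ratio < 0)
    return pd.DataFrame({"p": pvals, "log_ratio": ratio, "alpha_granule": label})


def build_table(
    t: pd.DataFrame,
    p_thresh: float = DEFAULT_P_THRESH,
    fpkm_thresh: float = DEFAULT_FPKM_THRESH,
) -> np.ndarray:
    """Cross-classify significant effects by granule label x effect sign.

    Restricts to proteins with expression above ``fpkm_thresh`` and
    association p below ``p_thresh``; returns the 2x2 count matrix
    [[granule & negative, granule & positive],
     [other & negative,   other & positive]].
    """
    if t.empty:
        raise ValueError("protein effect table is empty")
    sel = t.loc[(t["log2_fpkm"] > fpkm_thresh) & (t["p"] < p_thresh)]
    if (sel["beta"] == 0).any():
        sel = sel.loc[sel["beta"] != 0]
    gran = sel["alpha_granule"].astype(bool)
    neg = sel["beta"] < 0
    return np.array(
        [
            [int((gran & neg).sum()), int((gran & ~neg).sum())],
            [int((~gran & neg).sum()), int((~gran & ~neg).sum())],
        ]
    )


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p: total hypergeometric probability of
    tables (at fixed margins) no more likely than the observed one.

    A zero margin makes every table equally compatible; p = 1 with a
    warning.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin; Fisher p set to 1", stacklevel=2)
        return 1.0
    return float(_scipy_fisher(tab, alternative="two-sided").pvalue)


def localisation_regression(t: pd.DataFrame) -> dict[str, float]:
    """Effect of granule localisation on the allelic effect size,
    adjusted for megakaryocyte expression.

    OLS of the per-protein effect estimate on the alpha-granule
    indicator plus log2 FPKM; returns the indicator's coefficient with
    its standard error and two-sided t-test p-value.
    """
    gran = t["alpha_granule"].astype(float)
    if gran.nunique() < 2:
        raise ValueError("both granule label groups must be present")
    x = sm.add_constant(
        pd.DataFrame({"alpha_granule": gran, "log2_fpkm": t["log2_fpkm"].astype(float)})
    )
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("collinear design: label perfectly predicted by expression")
    fit = sm.OLS(t["beta"].astype(float), x).fit()
    return {
        "coef": float(fit.params["alpha_granule"]),
        "se": float(fit.bse["alpha_granule"]),
        "p": float(fit.pvalues["alpha_granule"]),
    }
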