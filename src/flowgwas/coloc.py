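"""Regional colocalisation of two association signals.

Given regional summary statistics for a blood-cell trait and a partner
trait (an eQTL, pQTL or disease association), the regional model
compares five hypotheses: no association, trait 1 only, trait 2 only,
two distinct causal variants, and a single shared causal variant.
Per-variant evidence enters through Wakefield's approximate Bayes
factor; regional likelihoods sum over variant assignments with
per-variant priors (p1, p2, p12).  A shared-signal posterior above 0.8
is called a colocalisation, as in the source workflow.

Regions with several conditionally significant variants are first
reduced to single-signal statistics by regressing the trait on the
conditional variants not in strong LD with the variant of interest and
re-scanning the residuals (:func:`residualize_secondary`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import run_univariable
from .clumping import ld_r2
from .synthdata import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_PP_GATE = 0.8


@dataclass
class ColocPriors:
    """Per-variant priors for the regional model.

    ``p1``/``p2``: prior that a given variant is causal for trait 1/2
    alone; ``p12``: prior that it is causal for both.  ``w1``/``w2``:
    prior variance of the (standardised) effect size for each trait.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.01
    w2: float = 0.01

    def validate(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("per-variant priors must sum to less than 1")
        if min(self.w1, self.w2) < 0:
            raise ValueError("effect prior variances must be non-negative")


@dataclass
class ColocResult:
    n_variants: int
    pp: dict[str, float]  # H0..H4 posteriors, summing to 1
    shared_pp: float
    passes: bool


def abf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Log approximate Bayes factor for association at one variant.

    log BF = 0.5*log(se^2/(se^2+W)) + z^2/2 * W/(se^2+W), the standard
    Gaussian approximation with effect prior variance W.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if w < 0:
        raise ValueError("prior variance must be non-negative")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + 0.5 * z2 * (w / (v + w))


def _logsumexp(x: np.ndarray) -> float:
    mx = np.max(x)
    return float(mx + np.log(np.sum(np.exp(x - mx))))


def pairwise_pp(
    stats_1: pd.DataFrame,
    stats_2: pd.DataFrame,
    priors: ColocPriors | None = None,
    pp_gate: float = DEFAULT_PP_GATE,
) -> ColocResult:
    """Posterior probabilities of the five regional hypotheses.

    Inputs are summary-statistic frames with columns (id, beta, se),
    intersected on id.  The shared model sums per-variant products of
    the two traits' Bayes factors; the distinct model sums over ordered
    pairs of different variants.
    """
    priors = priors or ColocPriors()
    priors.validate()
    merged = stats_1.merge(stats_2, on="id", suffixes=("_1", "_2"))
    m = len(merged)
    if m < 2:
        raise ValueError("need at least two shared variants for a regional model")

    l1 = abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), priors.w1)
    l2 = abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), priors.w2)

    s1 = _logsumexp(l1)
    s2 = _logsumexp(l2)
    s12 = _logsumexp(l1 + l2)
    # sum over ordered distinct pairs: S1*S2 - sum_j BF1_j*BF2_j
    # (S1*S2 >= S12 always, since it contains every diagonal term)
    gap = s12 - (s1 + s2)
    distinct = s1 + s2 + np.log1p(-np.exp(gap)) if gap < -1e-12 else -np.inf

    logs = {
        "H0": 0.0,
        "H1": np.log(priors.p1) + s1,
        "H2": np.log(priors.p2) + s2,
        "H3": np.log(priors.p1) + np.log(priors.p2) + distinct,
        "H4": np.log(priors.p12) + s12,
    }
    keys = list(logs)
    vec = np.array([logs[k] for k in keys])
    vec -= _logsumexp(vec)
    pp = {k: float(np.exp(v)) for k, v in zip(keys, vec)}
    shared = pp["H4"]
    return ColocResult(n_variants=m, pp=pp, shared_pp=shared, passes=shared > pp_gate)


def residualize_secondary(
    trait: np.ndarray,
    g: GenotypeMatrix,
    conditional_ids: list[str],
    target: str,
    covariates: np.ndarray | None = None,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Single-signal regional statistics for one conditional variant.

    The trait is regressed on the region's other conditionally
    significant variants — excluding any in strong LD (r^2 >
    ``r2_threshold``) with the target — and the residuals are re-scanned
    univariably across the region.  If every other conditional variant
    is in LD with the target, no adjustment is made (identity, logged).
    """
    if target not in conditional_ids:
        raise ValueError("target must be one of the region's conditional variants")
    tvec = g.column(target)
    others = []
    for vid in conditional_ids:
        if vid == target:
            continue
        if ld_r2(g.column(vid), tvec) > r2_threshold:
            continue
        others.append(vid)

    y = np.asarray(trait, dtype=float)
    if others:
        x = np.column_stack([np.ones(len(y))] + [g.column(v) for v in others])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        y = y - x @ coef + y.mean()
    else:
        logger.info("no independent secondary signals for %s; scan unadjusted", target)
    return run_univariable(y, g, covariates)


def lead_ld_gate(dosage_lead_1: np.ndarray, dosage_lead_2: np.ndarray, r2_min: float = 0.8) -> bool:
    """Pre-gate: only regions whose two lead variants are in strong LD
    proceed to the regional computation."""
    return ld_r2(dosage_lead_1, dosage_lead_2) > r2_min
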