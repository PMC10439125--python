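"""Block-wise Efroymson stepwise conditional selection.

Genome-wide-significant variants are partitioned into blocks such that
variants in distinct blocks are at least 10 Mb apart (single-linkage on
the gap relation, never across chromosomes).  Within each block an
Efroymson forward/backward stepwise regression selects variants whose
likelihood-ratio p-value beats the genome-wide threshold, subject to an
LD cap: a candidate correlated at r^2 above 0.9 with any model member is
never admitted.  A final elimination-first pass over the union of the
block selections yields the trait's conditionally significant variants
with their joint effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import t as t_dist

from .assoc import residualize
from .clumping import ld_r2

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 8.31e-9
DEFAULT_R2_CAP = 0.9
DEFAULT_BLOCK_GAP = 10_000_000


def partition_blocks(positions: pd.DataFrame, gap: int = DEFAULT_BLOCK_GAP) -> np.ndarray:
    """Assign block labels by single-linkage clustering of positions.

    Two variants share a block iff they sit on the same chromosome and
    are connected by a chain of neighbours each closer than ``gap``.
    Returns an integer block id per row of ``positions`` (columns
    ``chrom`` and ``pos``).
    """
    labels = np.full(len(positions), -1, dtype=int)
    block = 0
    for _, idx in positions.groupby("chrom", sort=True).groups.items():
        sub = positions.loc[idx].sort_values("pos")
        prev_pos = None
        for row_label, pos in zip(sub.index, sub["pos"]):
            if prev_pos is not None and pos - prev_pos >= gap:
                block += 1
            labels[positions.index.get_loc(row_label)] = block
            prev_pos = pos
        block += 1
    return labels


def _lr_pvalue(rss0: float, rss1: float, n: int) -> float:
    """Likelihood-ratio p from the chi-squared(1) statistic n*ln(RSS0/RSS1)."""
    if rss1 <= 0 or rss0 <= rss1:
        return 1.0 if rss0 <= rss1 else 0.0
    return float(chi2.sf(n * np.log(rss0 / rss1), df=1))


def _rss(y: np.ndarray, x: np.ndarray | None) -> float:
    if x is None or x.shape[1] == 0:
        return float(np.sum((y - y.mean()) ** 2))
    xc = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
    return float(np.sum((y - xc @ beta) ** 2))


@dataclass
class StepRecord:
    action: str  # 'add' or 'drop'
    variant: str
    p: float


@dataclass
class ConditionalModel:
    """Terminating stepwise model for one trait."""

    trait: str
    variants: list[str]
    table: pd.DataFrame  # variant, block, beta, se, p (joint fit)
    history: list[StepRecord] = field(default_factory=list)


def _order_key(pos: dict[str, tuple[str, int]], descending: bool = False):
    """Sort key on (p, coordinate, id); ties always break by smaller
    genomic coordinate then lexicographic id, whichever way p sorts."""

    def key(item):
        p, vid = item
        chrom, bp = pos.get(vid, ("", 0))
        return (-p if descending else p, chrom, bp, vid)

    return key


def _stepwise_loop(
    y: np.ndarray,
    x: np.ndarray,
    ids: list[str],
    positions: dict[str, tuple[str, int]],
    alpha: float,
    r2_cap: float,
    initial: list[str],
    start_at_elimination: bool,
) -> tuple[list[str], list[StepRecord]]:
    col = {vid: j for j, vid in enumerate(ids)}
    members = [v for v in initial if v in col]
    history: list[StepRecord] = []
    n = len(y)

    def design(vs: list[str]) -> np.ndarray | None:
        return x[:, [col[v] for v in vs]] if vs else None

    def eliminate() -> None:
        while members:
            rss_full = _rss(y, design(members))
            drops = []
            for v in members:
                rest = [w for w in members if w != v]
                p = _lr_pvalue(_rss(y, design(rest)), rss_full, n)
                drops.append((p, v))
            drops.sort(key=_order_key(positions, descending=True))
            worst_p, worst_v = drops[0]
            if worst_p > alpha:
                members.remove(worst_v)
                history.append(StepRecord("drop", worst_v, worst_p))
            else:
                return

    if start_at_elimination:
        eliminate()

    while True:
        rss0 = _rss(y, design(members))
        adds = []
        for v in ids:
            if v in members:
                continue
            if any(ld_r2(x[:, col[v]], x[:, col[w]]) > r2_cap for w in members):
                continue
            trial = design(members + [v])
            if np.linalg.matrix_rank(trial) <= (len(members) if members else 0):
                logger.info("candidate %s skipped: rank-deficient design", v)
                continue
            p = _lr_pvalue(rss0, _rss(y, trial), n)
            adds.append((p, v))
        adds.sort(key=_order_key(positions))
        if not adds or adds[0][0] >= alpha:
            break
        best_p, best_v = adds[0]
        members.append(best_v)
        history.append(StepRecord("add", best_v, best_p))
        eliminate()

    return members, history


def _joint_table(
    y: np.ndarray, x: np.ndarray, ids: list[str], members: list[str], blocks: dict[str, int]
) -> pd.DataFrame:
    if not members:
        return pd.DataFrame(columns=["variant", "block", "beta", "se", "p"])
    col = {vid: j for j, vid in enumerate(ids)}
    xm = np.column_stack([np.ones(len(y))] + [x[:, col[v]] for v in members])
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    resid = y - xm @ beta
    df = len(y) - xm.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.pinv(xm.T @ xm)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    p = 2 * t_dist.sf(np.abs(tstat), df=df)
    return pd.DataFrame(
        {
            "variant": members,
            "block": [blocks.get(v, -1) for v in members],
            "beta": beta[1:],
            "se": se[1:],
            "p": p[1:],
        }
    )


def efroymson_select(
    trait: np.ndarray,
    candidates: np.ndarray,
    ids: list[str],
    covariates: np.ndarray | None = None,
    positions: dict[str, tuple[str, int]] | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    r2_cap: float = DEFAULT_R2_CAP,
) -> tuple[list[str], list[StepRecord]]:
    """Forward/backward stepwise selection within one block.

    Covariates are projected out of trait and dosages first, which is
    equivalent to carrying them in every model.  P-value ties break by
    genomic coordinate then id, so the output is deterministic.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(candidates, dtype=float)
    if covariates is not None:
        y = residualize(y, covariates)
        x = x - covariates @ np.linalg.lstsq(covariates, x, rcond=None)[0]
    return _stepwise_loop(
        y, x, list(ids), positions or {}, alpha, r2_cap, initial=[], start_at_elimination=False
    )


def joint_refit(
    trait: np.ndarray,
    candidates: np.ndarray,
    ids: list[str],
    union: list[str],
    covariates: np.ndarray | None = None,
    positions: dict[str, tuple[str, int]] | None = None,
    blocks: dict[str, int] | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    r2_cap: float = DEFAULT_R2_CAP,
    trait_name: str = "trait",
) -> ConditionalModel:
    """Elimination-first stepwise over the pooled block selections."""
    y = np.asarray(trait, dtype=float)
    x = np.asarray(candidates, dtype=float)
    if covariates is not None:
        y = residualize(y, covariates)
        x = x - covariates @ np.linalg.lstsq(covariates, x, rcond=None)[0]
    members, history = _stepwise_loop(
        y,
        x,
        list(ids),
        positions or {},
        alpha,
        r2_cap,
        initial=list(union),
        start_at_elimination=True,
    )
    table = _joint_table(y, x, list(ids), members, blocks or {})
    return ConditionalModel(trait=trait_name, variants=members, table=table, history=history)


def conditional_analysis(
    trait: np.ndarray,
    dosages: np.ndarray,
    sumstats: pd.DataFrame,
    covariates: np.ndarray | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    gap: int = DEFAULT_BLOCK_GAP,
    r2_cap: float = DEFAULT_R2_CAP,
    trait_name: str = "trait",
) -> ConditionalModel:
    """Full conditional analysis for one trait.

    Selects the univariably genome-wide-significant variants from the
    summary statistics, partitions them into blocks, runs the stepwise
    selection per block, and refits the union with an elimination-first
    pass.
    """
    sig = sumstats.loc[sumstats["testable"] & (sumstats["p"] < alpha)].reset_index(drop=True)
    if sig.empty:
        return ConditionalModel(
            trait=trait_name,
            variants=[],
            table=pd.DataFrame(columns=["variant", "block", "beta", "se", "p"]),
        )
    block_ids = partition_blocks(sig[["chrom", "pos"]], gap=gap)
    id_list = sig["id"].tolist()
    pos_map = {r.id: (str(r.chrom), int(r.pos)) for r in sig.itertuples()}
    block_map = dict(zip(id_list, (int(b) for b in block_ids)))
    col_of = {vid: j for j, vid in enumerate(sumstats["id"])}
    x_all = dosages[:, [col_of[v] for v in id_list]]

    union: list[str] = []
    for b in sorted(set(block_map.values())):
        in_block = [v for v in id_list if block_map[v] == b]
        xs = dosages[:, [col_of[v] for v in in_block]]
        sel, _ = efroymson_select(
            trait, xs, in_block, covariates, pos_map, alpha=alpha, r2_cap=r2_cap
        )
        union.extend(sel)

    return joint_refit(
        trait,
        x_all,
        id_list,
        union,
        covariates,
        pos_map,
        block_map,
        alpha=alpha,
        r2_cap=r2_cap,
        trait_name=trait_name,
    )
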