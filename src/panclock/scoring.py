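"""Gene-set derivation and per-patient signature scoring.

The loss-of-function set ("clock-loss") collects genes that are recurrently
deleted across cancers *and* downregulated in tumour versus normal samples in
at least ``min_cancers`` cancer types; the gain-of-function set ("clock-gain")
is the amplified-and-upregulated counterpart. A patient's score for a set is
the unweighted mean of the log2 expression of its member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExprMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneSetDerivation:
    """Derived memberships plus the per-gene evidence behind them."""

    clock_loss: list[str]
    clock_gain: list[str]
    evidence: pd.DataFrame  # recurrence verdicts joined with concordance counts


def derive_gene_sets(recurrence: pd.DataFrame, concordance: pd.DataFrame,
                     min_cancers: int = 7) -> GeneSetDerivation:
    """Intersect recurrence and expression-concordance evidence.

    ``clock_loss = {g : recurrent_del(g) and n_cancers_down(g) >= min_cancers}``
    and symmetrically for ``clock_gain``. Gene universes are aligned on their
    intersection; an empty universe is an error, empty memberships only warn.
    """
    genes = recurrence.index.intersection(concordance.index)
    if len(genes) == 0:
        raise ValueError("recurrence and concordance tables share no genes")
    ev = recurrence.loc[genes].join(concordance.loc[genes])
    loss_mask = ev["recurrent_del"] & (ev["n_cancers_down"] >= min_cancers)
    gain_mask = ev["recurrent_amp"] & (ev["n_cancers_up"] >= min_cancers)
    clock_loss = list(ev.index[loss_mask])
    clock_gain = list(ev.index[gain_mask])
    both = set(clock_loss) & set(clock_gain)
    if both:
        logger.warning("genes satisfy both loss and gain criteria: %s",
                       sorted(both))
    if not clock_loss and not clock_gain:
        logger.warning("no genes passed gene-set derivation")
    ev = ev.copy()
    ev["in_clock_loss"] = loss_mask
    ev["in_clock_gain"] = gain_mask
    return GeneSetDerivation(clock_loss, clock_gain, ev)


def score_patients(expr, gene_set) -> pd.Series:
    """Per-sample mean log2 expression over the set genes present.

    Missing set genes are dropped with one warning listing them; if no set
    gene is present the score is undefined and an error is raised.
    """
    values = expr.values if isinstance(expr, ExprMatrix) else expr
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in values.index]
    missing = [g for g in gene_set if g not in values.index]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if missing:
        logger.warning("dropping %d set gene(s) absent from the matrix: %s",
                       len(missing), missing)
    return values.loc[present].mean(axis=0).rename("score")


def stratify(scores: pd.Series, mode: str = "quartile",
             partner_scores: pd.Series | None = None) -> pd.Series:
    """Assign stratification labels to scored samples.

    quartile
        Rank-based split into four near-equal groups (sizes differ by at most
        one), Q1 the lowest scores. Ties at a boundary are broken by stable
        sample order after ranking.
    median
        'high' iff score > median, else 'low' (a score equal to the median is
        'low').
    joint
        Cross of the two median labels of ``scores`` and ``partner_scores``,
        e.g. ``low/high`` = low primary score, high partner score.
    """
    scores = scores.dropna()
    if scores.nunique() <= 1:
        raise ValueError("all scores identical; no informative split")
    if mode == "quartile":
        if len(scores) < 4:
            raise ValueError("quartile stratification needs >= 4 samples")
        order = np.argsort(scores.to_numpy(), kind="stable")
        labels = pd.Series(index=scores.index, dtype=object)
        for qi, chunk in enumerate(np.array_split(order, 4)):
            labels.iloc[chunk] = f"Q{qi + 1}"
        return labels.rename("quartile")
    if mode == "median":
        med = scores.median()
        return pd.Series(np.where(scores > med, "high", "low"),
                         index=scores.index, name="median_group")
    if mode == "joint":
        if partner_scores is None:
            raise ValueError("joint mode requires partner_scores")
        a = stratify(scores, "median")
        b = stratify(partner_scores.reindex(scores.index).dropna(), "median")
        common = a.index.intersection(b.index)
        return (a.loc[common] + "/" + b.loc[common]).rename("joint_group")
    raise ValueError(f"unknown stratification mode {mode!r}")
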