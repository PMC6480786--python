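"""Recurrent copy-number alteration calling from discrete gene-level calls.

Per gene and cancer type the fraction of samples altered is tallied, counting
shallow and deep events ("any": call <= -1 or >= +1) and deep events alone
(call -2 or +2). A gene is recurrently deleted (amplified) when its deletion
(amplification) fraction reaches ``recurrence_fraction`` in at least
``min_cancers`` cancer types; both comparisons are inclusive.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import CNAMatrix, CohortBundle


def alteration_fractions(cna_by_cancer) -> pd.DataFrame:
    """Per-gene, per-cancer alteration fractions.

    Accepts a :class:`~panclock.io.CohortBundle` or a mapping of cancer type to
    :class:`~panclock.io.CNAMatrix`. Returns a DataFrame indexed by
    ``(gene, cancer_type)`` with columns ``frac_del_any``, ``frac_del_deep``,
    ``frac_amp_any``, ``frac_amp_deep`` and ``n_samples``.
    """
    if isinstance(cna_by_cancer, CohortBundle):
        mapping: Mapping[str, CNAMatrix] = {c.name: c.cna for c in cna_by_cancer}
    else:
        mapping = cna_by_cancer
    if not mapping:
        raise ValueError("no cancer types supplied")
    frames = []
    for ct, cna in mapping.items():
        calls = cna.calls if isinstance(cna, CNAMatrix) else cna
        n = calls.shape[1]
        if n == 0:
            raise ValueError(f"cancer type {ct} has zero samples")
        arr = calls.to_numpy()
        frames.append(pd.DataFrame({
            "gene": calls.index,
            "cancer_type": ct,
            "frac_del_any": (arr <= -1).sum(axis=1) / n,
            "frac_del_deep": (arr == -2).sum(axis=1) / n,
            "frac_amp_any": (arr >= 1).sum(axis=1) / n,
            "frac_amp_deep": (arr == 2).sum(axis=1) / n,
            "n_samples": n,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.set_index(["gene", "cancer_type"])


def classify_recurrent(fractions: pd.DataFrame,
                       recurrence_fraction: float = 0.20,
                       min_cancers: int = 7,
                       deletion_mode: str = "any") -> pd.DataFrame:
    """Per-gene recurrence verdicts from an alteration-fraction table.

    ``n_cancers_del`` counts cancer types whose deletion fraction is at least
    ``recurrence_fraction``; ``recurrent_del`` is true when that count reaches
    ``min_cancers``. Amplification verdicts are independent and symmetric.
    ``deletion_mode='deep_only'`` counts only -2/+2 calls.
    """
    if deletion_mode not in ("any", "deep_only"):
        raise ValueError("deletion_mode must be 'any' or 'deep_only'")
    n_cancers = fractions.index.get_level_values("cancer_type").nunique()
    if min_cancers > n_cancers:
        raise ValueError(f"min_cancers={min_cancers} exceeds the number of "
                         f"cancer types ({n_cancers})")
    suffix = "deep" if deletion_mode == "deep_only" else "any"
    hit_del = fractions[f"frac_del_{suffix}"] >= recurrence_fraction
    hit_amp = fractions[f"frac_amp_{suffix}"] >= recurrence_fraction
    n_del = hit_del.groupby(level="gene", sort=False).sum().astype(int)
    n_amp = hit_amp.groupby(level="gene", sort=False).sum().astype(int)
    genes = fractions.index.get_level_values("gene").unique()
    out = pd.DataFrame({
        "n_cancers_del": n_del.reindex(genes),
        "n_cancers_amp": n_amp.reindex(genes),
    }, index=genes.rename("gene"))
    out["recurrent_del"] = out["n_cancers_del"] >= min_cancers
    out["recurrent_amp"] = out["n_cancers_amp"] >= min_cancers
    return out[["recurrent_del", "n_cancers_del", "recurrent_amp", "n_cancers_amp"]]
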