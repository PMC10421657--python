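"""IGHV/IGHJ/IGHC segment usage: frequencies, differential tests, PCA.

Usage is the fraction of a sample's unique clonotypes assigned to each
gene segment (allele suffixes stripped, so ``IGHV3-30*03`` counts as
``IGHV3-30``). Differential usage between two sample groups uses the
Wilcoxon rank-sum test per segment (exact with midranks for small groups),
with Benjamini-Hochberg adjusted p-values reported alongside the raw ones;
segments are flagged at raw p < 0.05. Samples can then be ordinated by PCA
on the frequencies of a chosen segment subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test
from .records import ACTIVE_GROUPS, Cohort

logger = logging.getLogger(__name__)

FAMILY_COLUMN = {"V": "v_call", "J": "j_call", "C": "c_call"}


def strip_allele(call: str) -> str:
    """Reduce a segment call to gene level: first listed call, allele dropped."""
    return call.split(",")[0].split("*")[0].strip()


@dataclass
class UsageTable:
    """Samples x segments usage-frequency matrix with group labels."""

    frequencies: pd.DataFrame  # rows: sample_id, columns: segments
    groups: pd.Series  # sample_id -> group
    family: str
    isotype: str

    @property
    def segments(self) -> list:
        return list(self.frequencies.columns)


def usage_frequencies(cohort: Cohort, segment_family: str, isotype: str) -> UsageTable:
    """Per-sample usage frequency of each gene segment among unique clonotypes."""
    if segment_family not in FAMILY_COLUMN:
        raise ValueError(f"segment_family must be one of {sorted(FAMILY_COLUMN)}")
    col = FAMILY_COLUMN[segment_family]
    rows: Dict[str, Dict[str, float]] = {}
    groups: Dict[str, str] = {}
    n_dropped = 0
    for s in cohort.by_isotype(isotype):
        calls = s.df[col]
        valid = calls.notna() & (calls != "")
        n_dropped += int((~valid).sum())
        stripped = calls[valid].map(strip_allele)
        freq = stripped.value_counts(normalize=True)
        rows[s.sample_id] = freq.to_dict()
        groups[s.sample_id] = s.group
    if n_dropped:
        logger.info("usage_frequencies: excluded %d records with missing %s", n_dropped, col)
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table.reindex(sorted(table.columns), axis=1).sort_index()
    return UsageTable(table, pd.Series(groups).sort_index(), segment_family, isotype)


def active_disease_grouping(table_or_cohort) -> Dict[str, str]:
    """The disease-status preset: active (non-treated + treated patients)
    vs without disease (remission + endemic controls); non-endemic controls
    are not part of this contrast."""
    if isinstance(table_or_cohort, UsageTable):
        items = table_or_cohort.groups.items()
    else:
        items = table_or_cohort.metadata.items()
    out = {}
    for sid, group in items:
        if group in ACTIVE_GROUPS:
            out[sid] = "active"
        elif group in ("remission", "endemic_control"):
            out[sid] = "without_disease"
    return out


def differential_usage(
    table: UsageTable,
    grouping: Dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-segment two-group comparison of usage frequencies.

    Returns one row per segment: group means, rank-sum statistic, raw
    two-sided p, BH-adjusted p, and a ``flagged`` column at raw p < alpha.
    Segments absent from one status are still tested (against zeros) and
    noted.
    """
    statuses = sorted(set(grouping.values()))
    if len(statuses) != 2:
        raise ValueError(f"grouping must be binary, got statuses {statuses}")
    sa, sb = statuses
    ids_a = [s for s in table.frequencies.index if grouping.get(s) == sa]
    ids_b = [s for s in table.frequencies.index if grouping.get(s) == sb]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both statuses need at least two samples in the table")
    rows = []
    for seg in table.segments:
        a = table.frequencies.loc[ids_a, seg].to_numpy(float)
        b = table.frequencies.loc[ids_b, seg].to_numpy(float)
        stat, p = rank_sum_test(a, b)
        note = ""
        if not a.any():
            note = f"absent from all {sa} samples"
        elif not b.any():
            note = f"absent from all {sb} samples"
        rows.append(
            {
                "segment": seg,
                f"mean_{sa}": float(a.mean()),
                f"mean_{sb}": float(b.mean()),
                "statistic": stat,
                "p_value": p,
                "note": note,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"])
    out["flagged"] = out["p_value"] < alpha
    return out


@dataclass
class PCAResult:
    labels: tuple
    scores: np.ndarray
    loadings: np.ndarray  # segments x components
    explained_variance_ratio: np.ndarray
    segments: tuple


def usage_pca(
    table: UsageTable,
    segments: Optional[Sequence[str]] = None,
    n_components: int = 2,
) -> PCAResult:
    """PCA on (column-centered, unscaled) usage frequencies of chosen segments.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so scores are deterministic.
    """
    segments = list(segments) if segments is not None else table.segments
    missing = [s for s in segments if s not in table.frequencies.columns]
    if missing:
        raise KeyError(f"segments not in usage table: {missing}")
    X = table.frequencies[segments].to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2 / max(1, X.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    k = min(n_components, len(S))
    loadings = Vt[:k].T.copy()
    for comp in range(k):
        col = loadings[:, comp]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, comp] = -col
    scores = Xc @ loadings
    return PCAResult(
        tuple(table.frequencies.index),
        scores,
        loadings,
        ratio[:k],
        tuple(segments),
    )
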