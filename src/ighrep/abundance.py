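"""Clonal-expansion spectra: low / medium / hyperexpanded frequency bins.

Clonotypes are classified by their within-repertoire frequency: low
(< 0.1%), medium (0.1%-1%, both ends included), hyperexpanded (> 1%).
Proportions are computed over unique clonotypes, not abundance mass, and
bin proportions are compared between groups with a two-sample Wilcoxon
rank-sum test on per-sample proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .records import GROUPS, Cohort, RepertoireSample

BINS = ("low", "medium", "hyperexpanded")
LOW_THRESHOLD = 0.001
HYPER_THRESHOLD = 0.01


def bin_frequency(frequency: float) -> str:
    """Bin of a single clonotype frequency; the bins partition (0, 1]."""
    if frequency < LOW_THRESHOLD:
        return "low"
    if frequency > HYPER_THRESHOLD:
        return "hyperexpanded"
    return "medium"


@dataclass(frozen=True)
class AbundanceSpectrum:
    sample_id: str
    isotype: str
    counts: Dict[str, int]
    proportions: Dict[str, float]

    @property
    def n_clonotypes(self) -> int:
        return sum(self.counts.values())


def bin_clonotypes(sample: RepertoireSample) -> AbundanceSpectrum:
    """Tally the sample's clonotypes into the three frequency bins."""
    f = sample.frequencies
    low = int((f < LOW_THRESHOLD).sum())
    hyper = int((f > HYPER_THRESHOLD).sum())
    medium = len(f) - low - hyper
    counts = {"low": low, "medium": medium, "hyperexpanded": hyper}
    n = len(f)
    props = {b: (c / n if n else 0.0) for b, c in counts.items()}
    return AbundanceSpectrum(sample.sample_id, sample.isotype, counts, props)


def spectrum_table(cohort: Cohort, isotype: Optional[str] = None) -> pd.DataFrame:
    """Tidy per-sample spectrum table (sample_id, isotype, bin, count, proportion)."""
    rows = []
    for s in cohort.samples:
        if isotype is not None and s.isotype != isotype:
            continue
        spec = bin_clonotypes(s)
        for b in BINS:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "isotype": s.isotype,
                    "bin": b,
                    "count": spec.counts[b],
                    "proportion": spec.proportions[b],
                }
            )
    return pd.DataFrame(rows)


def compare_bin_proportions(
    cohort: Cohort,
    isotype: str,
    bin: str,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise group comparison of per-sample bin proportions.

    Uses the rank-sum test (exact with midranks when both groups have <= 8
    samples). Group pairs where either side has fewer than two samples are
    skipped with a warning.
    """
    if bin not in BINS:
        raise ValueError(f"unknown bin {bin!r}; expected one of {BINS}")
    groups = list(groups) if groups is not None else [g for g in GROUPS]
    per_group: Dict[str, list] = {g: [] for g in groups}
    for s in cohort.by_isotype(isotype):
        if s.group in per_group:
            per_group[s.group].append(bin_clonotypes(s).proportions[bin])
    rows = []
    for ga, gb in combinations(groups, 2):
        a, b = per_group[ga], per_group[gb]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"skipping {ga} vs {gb} for {isotype}/{bin}: fewer than 2 samples",
                stacklevel=2,
            )
            continue
        stat, p = rank_sum_test(a, b)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "isotype": isotype,
                "bin": bin,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
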