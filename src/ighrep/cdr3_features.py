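"""CDR3 length distributions and physicochemical characterization.

Length statistics are computed over unique clonotypes, unweighted by
abundance. Because CDR3 lengths are integers, the Shapiro-Wilk normality
test (which assumes a continuous variable) would reject a perfectly
Gaussian length model purely for its rounding; we therefore dither lengths
with seeded uniform noise on [-0.5, 0.5) before testing, which undoes the
discretization under the null while leaving real departures (skew, long
tails) detectable.

Chemistry per clonotype: GRAVY (mean Kyte-Doolittle hydropathy), net charge
at pH 7.0 by Henderson-Hasselbalch with the EMBOSS pKa set (termini
excluded -- the CDR3 is an internal fragment of the chain), aromatic
fraction (F, W, Y, H) and the aliphatic index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import stats

from ._stats import rank_sum_test
from .records import _AA_SET, Cohort, RepertoireSample

# EMBOSS ionizable side-chain pKa values
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
AROMATIC = frozenset("FWYH")


@dataclass(frozen=True)
class LengthDistribution:
    sample_id: str
    isotype: str
    histogram: Dict[int, float]  # length -> proportion of unique clonotypes
    median_length: float
    normality_p: Optional[float]  # None when fewer than 3 clonotypes


def length_distribution(
    sample: RepertoireSample,
    dither_seed: int = 0,
) -> LengthDistribution:
    """Histogram, median and Shapiro-Wilk normality p of CDR3 lengths."""
    lengths = sample.df["cdr3_aa"].str.len().to_numpy(int)
    if len(lengths) == 0:
        raise ValueError(f"empty repertoire {sample.key}")
    values, counts = np.unique(lengths, return_counts=True)
    hist = {int(v): float(c) / len(lengths) for v, c in zip(values, counts)}
    if len(lengths) < 3:
        warnings.warn(
            f"{sample.key}: fewer than 3 clonotypes, normality undefined", stacklevel=2
        )
        p = None
    else:
        rng = np.random.default_rng(dither_seed)
        dithered = lengths + rng.uniform(-0.5, 0.5, size=len(lengths))
        p = float(stats.shapiro(dithered).pvalue)
    return LengthDistribution(
        sample.sample_id, sample.isotype, hist, float(np.median(lengths)), p
    )


def compare_length_distributions(
    sample_a: RepertoireSample,
    sample_b: RepertoireSample,
) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on per-clonotype length vectors."""
    la = sample_a.df["cdr3_aa"].str.len().to_numpy(int)
    lb = sample_b.df["cdr3_aa"].str.len().to_numpy(int)
    if len(la) == 0 or len(lb) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(la, lb, method="auto")
    return float(res.statistic), float(res.pvalue)


def _net_charge(seq: str, ph: float = 7.0) -> float:
    charge = 0.0
    for aa, pka in PKA_POSITIVE.items():
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        charge -= seq.count(aa) / (1.0 + 10 ** (pka - ph))
    return charge


def chemistry(sample: RepertoireSample) -> pd.DataFrame:
    """Physicochemical properties per clonotype.

    Columns: cdr3_aa, length, gravy, net_charge, aromatic_fraction,
    aliphatic_index. Sequences with a non-standard residue are flagged
    (``valid`` False) and excluded from aggregate statistics downstream.
    """
    rows = []
    for seq in sample.df["cdr3_aa"]:
        valid = bool(seq) and set(seq) <= _AA_SET
        if not valid:
            rows.append(
                {
                    "cdr3_aa": seq, "length": len(seq), "gravy": np.nan,
                    "net_charge": np.nan, "aromatic_fraction": np.nan,
                    "aliphatic_index": np.nan, "valid": False,
                }
            )
            continue
        n = len(seq)
        gravy = sum(KYTE_DOOLITTLE[a] for a in seq) / n
        fa = seq.count("A") / n
        fv = seq.count("V") / n
        fil = (seq.count("I") + seq.count("L")) / n
        rows.append(
            {
                "cdr3_aa": seq,
                "length": n,
                "gravy": gravy,
                "net_charge": _net_charge(seq),
                "aromatic_fraction": sum(seq.count(a) for a in AROMATIC) / n,
                "aliphatic_index": 100.0 * (fa + 2.9 * fv + 3.9 * fil),
                "valid": True,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "sample_id", sample.sample_id)
    out.insert(1, "isotype", sample.isotype)
    return out


def length_table(cohort: Cohort, isotype: Optional[str] = None, dither_seed: int = 0) -> pd.DataFrame:
    """Tidy per-sample length summary (median, normality p) for a cohort."""
    rows = []
    for s in cohort.samples:
        if isotype is not None and s.isotype != isotype:
            continue
        dist = length_distribution(s, dither_seed=dither_seed)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "isotype": s.isotype,
                "n_clonotypes": s.n_clonotypes,
                "median_length": dist.median_length,
                "normality_p": dist.normality_p,
            }
        )
    return pd.DataFrame(rows)


def group_chemistry_comparison(cohort: Cohort, isotype: str) -> pd.DataFrame:
    """Pairwise group comparison (rank-sum) of per-sample mean chemistry."""
    per_sample = []
    for s in cohort.by_isotype(isotype):
        chem = chemistry(s)
        chem = chem[chem["valid"]]
        per_sample.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "gravy": chem["gravy"].mean(),
                "net_charge": chem["net_charge"].mean(),
                "aromatic_fraction": chem["aromatic_fraction"].mean(),
                "aliphatic_index": chem["aliphatic_index"].mean(),
            }
        )
    df = pd.DataFrame(per_sample)
    rows = []
    properties = ["gravy", "net_charge", "aromatic_fraction", "aliphatic_index"]
    for ga, gb in combinations(sorted(df["group"].unique()), 2):
        a_df, b_df = df[df["group"] == ga], df[df["group"] == gb]
        if len(a_df) < 2 or len(b_df) < 2:
            continue
        for prop in properties:
            stat, p = rank_sum_test(a_df[prop], b_df[prop])
            rows.append(
                {
                    "group_a": ga, "group_b": gb, "isotype": isotype,
                    "property": prop, "statistic": stat, "p_value": p,
                }
            )
    return pd.DataFrame(rows)
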