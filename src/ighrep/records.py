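"""Core data model: clonotype records, per-(sample, isotype) repertoires, cohorts.

A *clonotype* is a unique rearranged IGH sequence observed in one sample,
keyed by its CDR3 (nucleotide when available, else amino acid) together with
the V and J segment calls. A :class:`RepertoireSample` holds all clonotypes
of one sample for one isotype (IGHM or IGHG), with frequencies normalized
within that (sample, isotype) pair; IgM and IgG repertoires are analyzed
separately throughout.

Repertoires are backed by a pandas DataFrame for vectorized downstream
analysis; :class:`ClonotypeRecord` objects are materialized on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

GROUPS = ("nontreated", "treated", "remission", "endemic_control", "nonendemic_control")
PATIENT_GROUPS = ("nontreated", "treated", "remission")
ACTIVE_GROUPS = ("nontreated", "treated")
ENDEMIC_GROUPS = ("nontreated", "treated", "remission", "endemic_control")
ISOTYPES = ("IGHM", "IGHG")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)
_NT_SET = frozenset("ACGT")

#: columns of the repertoire table backing a RepertoireSample
TABLE_COLUMNS = ["cdr3_aa", "cdr3_nt", "v_call", "d_call", "j_call", "c_call", "count", "frequency"]


class ValidationError(ValueError):
    """A record or repertoire violates a structural invariant."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype observation in one (sample, isotype)."""

    sample_id: str
    group: str
    isotype: str
    cdr3_aa: str
    v_call: str
    j_call: str
    count: int
    frequency: float
    cdr3_nt: Optional[str] = None
    d_call: Optional[str] = None
    c_call: Optional[str] = None

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.isotype not in ISOTYPES:
            raise ValidationError(f"unknown isotype {self.isotype!r}")
        if not self.cdr3_aa:
            raise ValidationError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - _AA_SET
        if bad:
            raise ValidationError(f"invalid residues {sorted(bad)} in cdr3_aa {self.cdr3_aa!r}")
        if self.cdr3_nt is not None:
            if set(self.cdr3_nt) - _NT_SET:
                raise ValidationError(f"invalid nucleotides in cdr3_nt for {self.cdr3_aa!r}")
            if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
                raise ValidationError(
                    f"cdr3_nt length {len(self.cdr3_nt)} != 3 x cdr3_aa length {len(self.cdr3_aa)}"
                )
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        if not (0.0 < self.frequency <= 1.0):
            raise ValidationError(f"frequency must be in (0, 1], got {self.frequency}")

    @property
    def key(self) -> tuple:
        """Clonotype identity: (cdr3_nt if present else cdr3_aa, v_call, j_call)."""
        return (self.cdr3_nt if self.cdr3_nt else self.cdr3_aa, self.v_call, self.j_call)


def _key_frame(df: pd.DataFrame) -> pd.DataFrame:
    nt = df["cdr3_nt"] if "cdr3_nt" in df else pd.Series([None] * len(df), index=df.index)
    seq = nt.where(nt.notna() & (nt != ""), df["cdr3_aa"])
    return pd.DataFrame({"seq": seq, "v": df["v_call"], "j": df["j_call"]})


@dataclass
class RepertoireSample:
    """All clonotypes of one (sample, isotype), frequency-normalized.

    ``df`` has columns :data:`TABLE_COLUMNS`; ``count`` is the number of
    molecular-identifier groups (collapsed mRNA molecules) supporting the
    clonotype and ``frequency`` the clonotype's share of the repertoire.
    """

    sample_id: str
    group: str
    isotype: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"repertoire table missing columns {missing}")
        self.df = self.df[TABLE_COLUMNS].reset_index(drop=True)

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[ClonotypeRecord]) -> "RepertoireSample":
        records = list(records)
        if not records:
            raise ValidationError("cannot build a RepertoireSample from zero records")
        first = records[0]
        rows = []
        for r in records:
            if (r.sample_id, r.isotype) != (first.sample_id, first.isotype):
                raise ValidationError("records span multiple (sample, isotype) pairs")
            rows.append(
                {
                    "cdr3_aa": r.cdr3_aa,
                    "cdr3_nt": r.cdr3_nt,
                    "v_call": r.v_call,
                    "d_call": r.d_call,
                    "j_call": r.j_call,
                    "c_call": r.c_call,
                    "count": r.count,
                    "frequency": r.frequency,
                }
            )
        return cls(first.sample_id, first.group, first.isotype, pd.DataFrame(rows))

    # -- accessors -----------------------------------------------------
    @property
    def records(self) -> Iterator[ClonotypeRecord]:
        for row in self.df.itertuples(index=False):
            yield ClonotypeRecord(
                sample_id=self.sample_id,
                group=self.group,
                isotype=self.isotype,
                cdr3_aa=row.cdr3_aa,
                cdr3_nt=row.cdr3_nt if isinstance(row.cdr3_nt, str) and row.cdr3_nt else None,
                v_call=row.v_call,
                d_call=row.d_call if isinstance(row.d_call, str) and row.d_call else None,
                j_call=row.j_call,
                c_call=row.c_call if isinstance(row.c_call, str) and row.c_call else None,
                count=int(row.count),
                frequency=float(row.frequency),
            )

    @property
    def n_clonotypes(self) -> int:
        return len(self.df)

    @property
    def total_migs(self) -> int:
        return int(self.df["count"].sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.df["frequency"].to_numpy(float)

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.isotype)

    def validate(self, check_frequency_sum: bool = True) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for sample {self.sample_id}")
        if self.isotype not in ISOTYPES:
            raise ValidationError(f"unknown isotype {self.isotype!r} for sample {self.sample_id}")
        if len(self.df) == 0:
            raise ValidationError(f"empty repertoire for {self.key}")
        if (self.df["count"] < 1).any():
            raise ValidationError(f"non-positive clonotype count in {self.key}")
        if (self.df["frequency"] <= 0).any():
            raise ValidationError(f"non-positive frequency in {self.key}")
        if check_frequency_sum:
            total = float(self.df["frequency"].sum())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"frequencies of {self.key} sum to {total}, expected 1")
        keys = _key_frame(self.df)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValidationError(f"duplicated clonotype key {tuple(dup)} in {self.key}")

    def renormalized(self) -> "RepertoireSample":
        """Copy with frequency := count / total count."""
        df = self.df.copy()
        df["frequency"] = df["count"] / df["count"].sum()
        return RepertoireSample(self.sample_id, self.group, self.isotype, df)


@dataclass
class Cohort:
    """A set of repertoires plus the sample -> group metadata map."""

    samples: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self, check_frequency_sum: bool = True) -> None:
        seen = set()
        for s in self.samples:
            if s.sample_id not in self.metadata:
                raise ValidationError(f"sample {s.sample_id} missing from metadata")
            if self.metadata[s.sample_id] != s.group:
                raise ValidationError(f"group mismatch for sample {s.sample_id}")
            if s.key in seen:
                raise ValidationError(f"duplicate repertoire {s.key}")
            seen.add(s.key)
            s.validate(check_frequency_sum=check_frequency_sum)
        for sid, g in self.metadata.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r} for sample {sid}")

    # -- selection helpers --------------------------------------------
    def by_isotype(self, isotype: str) -> list:
        return [s for s in self.samples if s.isotype == isotype]

    def get(self, sample_id: str, isotype: str) -> RepertoireSample:
        for s in self.samples:
            if s.key == (sample_id, isotype):
                return s
        raise KeyError((sample_id, isotype))

    def subset(self, groups: Iterable[str]) -> "Cohort":
        groups = set(groups)
        samples = [s for s in self.samples if s.group in groups]
        meta = {sid: g for sid, g in self.metadata.items() if g in groups}
        return Cohort(samples, meta)

    def sample_ids(self, groups: Optional[Iterable[str]] = None) -> list:
        groups = set(groups) if groups is not None else set(GROUPS)
        return sorted({sid for sid, g in self.metadata.items() if g in groups})

    @property
    def patient_sample_ids(self) -> list:
        return self.sample_ids(PATIENT_GROUPS)

    @property
    def endemic_sample_ids(self) -> list:
        return self.sample_ids(ENDEMIC_GROUPS)


def merge_duplicate_clonotypes(sample: RepertoireSample) -> RepertoireSample:
    """Collapse rows sharing a clonotype key: counts summed, frequencies recomputed."""
    keys = _key_frame(sample.df)
    if not keys.duplicated().any():
        return sample
    df = sample.df.copy()
    grouped = df.groupby([keys["seq"], keys["v"], keys["j"]], sort=False)
    rows = []
    for _, sub in grouped:
        row = sub.iloc[0].copy()
        row["count"] = int(sub["count"].sum())
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["frequency"] = out["count"] / out["count"].sum()
    warnings.warn(
        f"merged {len(df) - len(out)} duplicated clonotype rows in {sample.key}",
        stacklevel=2,
    )
    return RepertoireSample(sample.sample_id, sample.group, sample.isotype, out)
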