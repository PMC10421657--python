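"""Reading and writing clonotype tables (AIRR Rearrangement TSV) and metadata.

The on-disk format follows the AIRR Rearrangement convention: one row per
clonotype per (sample, isotype), tab-separated, UTF-8, with ``junction_aa``
/ ``junction`` holding the CDR3 amino-acid / nucleotide sequence and
``duplicate_count`` the number of molecular-identifier groups. A separate
metadata TSV maps ``sample_id`` to its cohort ``group``.

Isotype is taken from an explicit ``isotype`` column when present, else
derived from the constant-region call (``c_call`` starting with IGHM/IGHG;
merged subclass labels such as ``IGHG3/4`` are preserved verbatim).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .records import (
    GROUPS,
    TABLE_COLUMNS,
    Cohort,
    RepertoireSample,
    ValidationError,
    merge_duplicate_clonotypes,
)

PathLike = Union[str, Path]

#: stable column order of the emitted rearrangement TSV
AIRR_COLUMNS = [
    "sequence_id",
    "sample_id",
    "isotype",
    "junction_aa",
    "junction",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "duplicate_count",
    "frequency",
]

MANDATORY_COLUMNS = ["sample_id", "junction_aa", "v_call", "j_call", "duplicate_count"]


class AirrFormatError(ValueError):
    """The rearrangement TSV is structurally malformed."""


class MetadataError(ValueError):
    """The metadata table is inconsistent with the rearrangement table."""


def read_metadata(path: PathLike) -> dict:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise AirrFormatError(f"metadata is missing mandatory column {col!r}")
    mapping = {}
    for row in meta.itertuples(index=False):
        if row.group not in GROUPS:
            raise MetadataError(
                f"unknown group label {row.group!r} for sample {row.sample_id!r}; "
                f"expected one of {GROUPS}"
            )
        mapping[row.sample_id] = row.group
    return mapping


def _isotype_of(row_isotype: Optional[str], c_call: Optional[str], context: str) -> str:
    if isinstance(row_isotype, str) and row_isotype:
        return row_isotype
    if isinstance(c_call, str) and c_call:
        for iso in ("IGHM", "IGHG"):
            if c_call.startswith(iso):
                return iso
    raise AirrFormatError(f"cannot determine isotype for {context}: no isotype or c_call")


def read_airr(
    path: PathLike,
    metadata_path: PathLike,
    validate: bool = True,
) -> Cohort:
    """Read a rearrangement TSV plus metadata TSV into a validated Cohort.

    Frequencies are recomputed as ``count / total count`` per (sample,
    isotype) when the ``frequency`` column is absent, and preserved verbatim
    when present (so filtered tables round-trip unchanged). Rows duplicating
    a clonotype key within a sample are merged with counts summed.
    """
    metadata = read_metadata(metadata_path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"junction_aa": str, "junction": str},
        na_filter=True,
        float_precision="round_trip",
    )
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise AirrFormatError(f"rearrangement table is missing mandatory column {col!r}")
    if len(df) and (df["duplicate_count"] <= 0).any():
        bad = df.index[df["duplicate_count"] <= 0][0]
        raise ValidationError(f"non-positive duplicate_count at row {bad}")

    has_freq = "frequency" in df.columns

    def _opt(row, name):
        v = getattr(row, name, None)
        return v if isinstance(v, str) and v else None

    samples = []
    if len(df):
        iso = [
            _isotype_of(_opt(r, "isotype"), _opt(r, "c_call"), f"row {i}")
            for i, r in enumerate(df.itertuples(index=False))
        ]
        df = df.assign(_isotype=iso)
        for (sid, isotype), sub in df.groupby(["sample_id", "_isotype"], sort=False):
            if sid not in metadata:
                raise MetadataError(f"sample {sid!r} absent from metadata")
            table = pd.DataFrame(
                {
                    "cdr3_aa": sub["junction_aa"].astype(str),
                    "cdr3_nt": sub["junction"] if "junction" in sub else None,
                    "v_call": sub["v_call"].astype(str),
                    "d_call": sub["d_call"] if "d_call" in sub else None,
                    "j_call": sub["j_call"].astype(str),
                    "c_call": sub["c_call"] if "c_call" in sub else None,
                    "count": sub["duplicate_count"].astype(int),
                    "frequency": sub["frequency"].astype(float) if has_freq else 0.0,
                }
            )
            if not has_freq:
                table["frequency"] = table["count"] / table["count"].sum()
            sample = RepertoireSample(sid, metadata[sid], isotype, table)
            sample = merge_duplicate_clonotypes(sample)
            samples.append(sample)

    cohort = Cohort(samples, metadata)
    if validate:
        cohort.validate(check_frequency_sum=not has_freq or _sums_ok(cohort))
    return cohort


def _sums_ok(cohort: Cohort) -> bool:
    return all(abs(float(s.df["frequency"].sum()) - 1.0) <= 1e-9 for s in cohort.samples)


def write_airr(
    cohort: Cohort,
    path: PathLike,
    metadata_path: Optional[PathLike] = None,
) -> None:
    """Write the cohort as a rearrangement TSV (stable column order).

    Round-trips losslessly through :func:`read_airr`: counts, calls and
    sequences are written verbatim; an empty cohort yields a header-only file.
    """
    frames = []
    seq_no = 0
    for s in cohort.samples:
        out = pd.DataFrame(
            {
                "sequence_id": [f"seq{seq_no + i}" for i in range(len(s.df))],
                "sample_id": s.sample_id,
                "isotype": s.isotype,
                "junction_aa": s.df["cdr3_aa"],
                "junction": s.df["cdr3_nt"],
                "v_call": s.df["v_call"],
                "d_call": s.df["d_call"],
                "j_call": s.df["j_call"],
                "c_call": s.df["c_call"],
                "duplicate_count": s.df["count"],
                "frequency": s.df["frequency"],
            }
        )
        seq_no += len(s.df)
        frames.append(out)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=AIRR_COLUMNS)
    )
    table[AIRR_COLUMNS].to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        meta = pd.DataFrame(
            sorted(cohort.metadata.items()), columns=["sample_id", "group"]
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def filter_by_frequency(
    sample: RepertoireSample,
    min_frequency: float,
    renormalize: bool = False,
) -> RepertoireSample:
    """Keep clonotypes with frequency strictly greater than ``min_frequency``.

    Frequencies are left untouched unless ``renormalize`` is set; the
    operation is idempotent at a fixed threshold.
    """
    if not (0.0 <= min_frequency < 1.0):
        raise ValueError(f"min_frequency must be in [0, 1), got {min_frequency}")
    df = sample.df[sample.df["frequency"] > min_frequency].reset_index(drop=True)
    out = RepertoireSample(sample.sample_id, sample.group, sample.isotype, df)
    if renormalize and len(df):
        df = df.copy()
        df["frequency"] = df["frequency"] / df["frequency"].sum()
        out = RepertoireSample(sample.sample_id, sample.group, sample.isotype, df)
    if len(df) == 0:
        warnings.warn(f"frequency filter removed every clonotype of {sample.key}", stacklevel=2)
    return out
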