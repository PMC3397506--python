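"""Core data types and I/O for compound tables.

A dataset couples, per compound, an oral bioavailability measurement
(%F, the fraction of an oral dose reaching systemic circulation),
docking-derived binding scores against the disposition proteins
(CYP3A4, CYP2D6, P-glycoprotein), and a numeric molecular-descriptor
vector.  The regression target throughout the package is
``logB = log10(%F)``, which linearises the strongly right-skewed
bioavailability scale.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "FormatError",
    "ConsistencyError",
    "CompoundRecord",
    "CompoundDataset",
    "EvaluationReport",
    "ColumnSchema",
    "transform_ob_to_logb",
    "average_duplicate_ob",
    "load_compound_table",
    "write_compound_table",
    "reports_to_frame",
    "write_reports",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the schema mapping is invalid."""


class FormatError(ValueError):
    """The file violates the tabular format contract (e.g. duplicate columns)."""


class ConsistencyError(ValueError):
    """Duplicate records disagree where they are required to agree."""


def transform_ob_to_logb(ob_percent: float) -> float:
    """Common logarithm of an oral bioavailability percentage.

    Parameters
    ----------
    ob_percent
        %F in (0, 100].

    Returns
    -------
    float
        ``log10(ob_percent)`` — e.g. 100 % maps to 2.0, 1 % to 0.0.
    """
    if ob_percent <= 0:
        raise ValueError(f"ob_percent must be > 0 to take log10, got {ob_percent}")
    return math.log10(ob_percent)


@dataclass
class CompoundRecord:
    """One molecule: identity, bioavailability, binding scores, descriptors."""

    compound_id: str
    ob_percent: float
    binding_scores: dict[str, float]
    descriptors: dict[str, float]

    @property
    def logb(self) -> float:
        return transform_ob_to_logb(self.ob_percent)


@dataclass
class CompoundDataset:
    """An ordered compound collection with a rectangular descriptor block."""

    records: list[CompoundRecord]
    descriptor_names: list[str]
    provenance: str = ""
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise FormatError("descriptor names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def descriptor_matrix(self) -> np.ndarray:
        """Dense (n_compounds, n_descriptors) float matrix in dataset order."""
        out = np.empty((len(self.records), len(self.descriptor_names)))
        for i, rec in enumerate(self.records):
            try:
                out[i] = [rec.descriptors[name] for name in self.descriptor_names]
            except KeyError as exc:  # rectangularity invariant
                raise FormatError(
                    f"record {rec.compound_id!r} is missing descriptor {exc}"
                ) from exc
        return out

    def logb_vector(self) -> np.ndarray:
        return np.array([r.logb for r in self.records])

    def binding_score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.binding_scores for r in self.records], index=self.compound_ids
        )

    def subset(self, indices: Sequence[int], provenance: str = "") -> "CompoundDataset":
        return CompoundDataset(
            records=[self.records[i] for i in indices],
            descriptor_names=list(self.descriptor_names),
            provenance=provenance or self.provenance,
        )


@dataclass
class EvaluationReport:
    """Per-subset, per-model goodness-of-fit and prediction statistics.

    ``r2_train`` and ``q2_ex`` are squared Pearson correlations between
    observed and predicted logB on the training and test set; ``see`` is the
    degrees-of-freedom-corrected training standard error of estimation and
    ``sep`` the test-set root-mean-square error of prediction, both in logB
    units.
    """

    subset_id: str
    model_name: str
    r2_train: float
    q2_ex: float
    see: float
    sep: float
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        if self.see < 0 or self.sep < 0:
            raise ValueError("see and sep must be non-negative")


def average_duplicate_ob(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse repeated measurements of the same compound.

    Replicated bioavailability entries are averaged on the %F scale (before
    the log transform), which is not the same as averaging logB.  Duplicates
    must carry identical descriptors and binding scores; order of first
    appearance is preserved.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.compound_id not in groups:
            groups[rec.compound_id] = []
            order.append(rec.compound_id)
        groups[rec.compound_id].append(rec)

    out: list[CompoundRecord] = []
    for cid in order:
        grp = groups[cid]
        first = grp[0]
        for other in grp[1:]:
            if other.descriptors != first.descriptors:
                raise ConsistencyError(
                    f"duplicate entries for {cid!r} have conflicting descriptors"
                )
            if other.binding_scores != first.binding_scores:
                raise ConsistencyError(
                    f"duplicate entries for {cid!r} have conflicting binding scores"
                )
        if len(grp) == 1:
            out.append(first)
        else:
            mean_ob = float(np.mean([r.ob_percent for r in grp]))
            out.append(
                CompoundRecord(
                    compound_id=cid,
                    ob_percent=mean_ob,
                    binding_scores=dict(first.binding_scores),
                    descriptors=dict(first.descriptors),
                )
            )
    return out


@dataclass
class ColumnSchema:
    """Binds the free-form column names of an input table to their roles.

    ``binding_scores`` maps a protein label (e.g. ``"cyp3a4"``) to the column
    holding its score.  ``descriptors=None`` means "every remaining column".
    """

    compound_id: str = "compound_id"
    ob_percent: str = "ob_percent"
    binding_scores: dict[str, str] = field(
        default_factory=lambda: {
            "cyp3a4": "score_cyp3a4",
            "cyp2d6": "score_cyp2d6",
            "pgp": "score_pgp",
        }
    )
    descriptors: list[str] | None = None


def _detect_sep(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt", ".tab")) else ","


def load_compound_table(
    path: str,
    schema: ColumnSchema | None = None,
    *,
    missing_column_threshold: float = 0.05,
) -> CompoundDataset:
    """Read a delimited compound table into a :class:`CompoundDataset`.

    Rows with unparseable or out-of-range %F (≤ 0, > 100, or non-numeric)
    are rejected and listed, with their 0-based row index and reason, in the
    returned dataset's ``rejected_rows``.  Descriptor columns with more than
    ``missing_column_threshold`` missing values are dropped; rows with any
    remaining missing descriptor are then dropped.  CSV vs TSV is detected
    from the file extension.
    """
    schema = schema or ColumnSchema()
    sep_char = _detect_sep(path)
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter=sep_char))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"duplicate column names: {dupes}")
    df = pd.read_csv(path, sep=sep_char)

    for role, col in (("compound_id", schema.compound_id), ("ob_percent", schema.ob_percent)):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} ({role}) not found")
    score_cols = {}
    for protein, col in schema.binding_scores.items():
        if col in df.columns:
            score_cols[protein] = col
    if not score_cols:
        raise SchemaError(
            f"none of the binding-score columns {list(schema.binding_scores.values())} found"
        )

    reserved = {schema.compound_id, schema.ob_percent, *score_cols.values()}
    if schema.descriptors is None:
        desc_cols = [c for c in df.columns if c not in reserved]
    else:
        missing = [c for c in schema.descriptors if c not in df.columns]
        if missing:
            raise SchemaError(f"descriptor columns not found: {missing}")
        desc_cols = list(schema.descriptors)

    rejected: list[tuple[int, str]] = []
    ob = pd.to_numeric(df[schema.ob_percent], errors="coerce")
    keep = np.ones(len(df), dtype=bool)
    for i in range(len(df)):
        v = ob.iloc[i]
        if not np.isfinite(v):
            rejected.append((i, "unparseable ob_percent"))
            keep[i] = False
        elif v > 100:
            rejected.append((i, f"ob_percent {v} > 100 (not a fraction of dose)"))
            keep[i] = False
        elif v <= 0:
            rejected.append((i, f"ob_percent {v} <= 0 (log10 undefined)"))
            keep[i] = False
    if any(r[1].startswith("ob_percent") and "<= 0" in r[1] for r in rejected):
        warnings.warn(
            "rows with ob_percent <= 0 were excluded from modelling", stacklevel=2
        )

    desc = df.loc[keep, desc_cols].apply(pd.to_numeric, errors="coerce")
    # missing-value policy: drop heavily-missing columns, then offending rows
    frac_missing = desc.isna().mean(axis=0) if len(desc) else pd.Series(dtype=float)
    drop_cols = [c for c in desc_cols if frac_missing.get(c, 0.0) > missing_column_threshold]
    if drop_cols:
        warnings.warn(
            f"dropping {len(drop_cols)} descriptor column(s) with "
            f"> {missing_column_threshold:.0%} missing values",
            stacklevel=2,
        )
        desc = desc.drop(columns=drop_cols)
        desc_cols = [c for c in desc_cols if c not in drop_cols]
    row_has_na = desc.isna().any(axis=1)
    for pos, bad in zip(np.flatnonzero(keep), row_has_na):
        if bad:
            rejected.append((int(pos), "missing descriptor value"))
            keep[pos] = False
    desc = desc.loc[~row_has_na.values]

    records: list[CompoundRecord] = []
    kept_idx = np.flatnonzero(keep)
    for j, i in enumerate(kept_idx):
        row = df.iloc[i]
        records.append(
            CompoundRecord(
                compound_id=str(row[schema.compound_id]),
                ob_percent=float(ob.iloc[i]),
                binding_scores={
                    p: float(row[c]) for p, c in score_cols.items() if pd.notna(row[c])
                },
                descriptors={c: float(desc.iloc[j][c]) for c in desc_cols},
            )
        )

    records = average_duplicate_ob(records)
    return CompoundDataset(
        records=records,
        descriptor_names=desc_cols,
        provenance=f"loaded from {path}",
        rejected_rows=sorted(rejected),
    )


def write_compound_table(dataset: CompoundDataset, path: str) -> None:
    """Write a dataset in the delimited layout :func:`load_compound_table` reads."""
    proteins = sorted({p for r in dataset.records for p in r.binding_scores})
    cols: dict[str, list] = {"compound_id": dataset.compound_ids}
    cols["ob_percent"] = [r.ob_percent for r in dataset.records]
    for p in proteins:
        cols[f"score_{p}"] = [r.binding_scores.get(p, np.nan) for r in dataset.records]
    df = pd.DataFrame(cols)
    desc = pd.DataFrame(
        dataset.descriptor_matrix(), columns=dataset.descriptor_names
    )
    pd.concat([df, desc], axis=1).to_csv(path, sep=_detect_sep(path), index=False)


def reports_to_frame(reports: Iterable[EvaluationReport]) -> pd.DataFrame:
    rows = [
        {
            "subset_id": r.subset_id,
            "model_name": r.model_name,
            "r2_train": r.r2_train,
            "q2_ex": r.q2_ex,
            "see": r.see,
            "sep": r.sep,
            "n_train": r.n_train,
            "n_test": r.n_test,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def write_reports(
    reports: Sequence[EvaluationReport], csv_path: str, json_path: str | None = None
) -> None:
    frame = reports_to_frame(reports)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
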