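"""Reading, writing and assembly of ligand-receptor interaction rank tables.

One row of an interaction table is a single inferred, *directed*
communication event in one biopsy: a sender cell type expressing a ligand
(possibly a multi-subunit complex) signalling to a receiver cell type
expressing a receptor.  Each inference method contributes an integer rank
(1 = strongest evidence); the consensus framework additionally emits an
aggregate rank in (0, 1] that behaves like a p-value.  The per-sample mean
rank -- the arithmetic mean of the per-method ranks -- is the quantity all
downstream modelling consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionKey",
    "RankedInteraction",
    "SampleAnnotation",
    "CANONICAL_METHODS",
    "compute_mean_rank",
    "interaction_score",
    "key_to_label",
    "label_to_key",
    "read_interaction_tables",
    "write_interaction_table",
    "read_metadata",
    "write_metadata",
    "build_rank_matrix",
]

#: Inference methods emulated by the synthetic generator; real tables may
#: carry any subset of ``<method>_rank`` columns.
CANONICAL_METHODS = ("natmi", "connectome", "logfc", "sca", "cellphonedb")

_REQUIRED_COLUMNS = (
    "sample_id",
    "source",
    "target",
    "ligand_complex",
    "receptor_complex",
    "aggregate_rank",
)

_TIMEPOINTS = frozenset({"pre", "post"})
_RESPONSES = frozenset({"R", "NR", "unknown"})


class ParseError(ValueError):
    """Malformed interaction table or metadata file."""


def _canonical_complex(subunits: Iterable[str]) -> tuple[str, ...]:
    units = tuple(sorted(str(s) for s in subunits))
    if not units or any(u == "" for u in units):
        raise ValueError("complex must contain at least one nonempty gene symbol")
    return units


@dataclass(frozen=True, order=True)
class InteractionKey:
    """Identity of a directed interaction: sender cell, receiver cell,
    ligand complex, receptor complex.

    The same ligand-receptor pair between two different cell-type pairs is a
    distinct key, because the analysis treats cell-type context as part of
    the feature.  Complex subunits are stored in a sorted canonical order so
    keys are stable across files.
    """

    sender: str
    receiver: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand", _canonical_complex(self.ligand))
        object.__setattr__(self, "receptor", _canonical_complex(self.receptor))

    @property
    def ligand_complex(self) -> str:
        return "_".join(self.ligand)

    @property
    def receptor_complex(self) -> str:
        return "_".join(self.receptor)

    def __str__(self) -> str:  # pragma: no cover - display helper
        return key_to_label(self)


def key_to_label(key: InteractionKey) -> str:
    """Serialize a key to the pipe-delimited column label used in matrices."""
    return "|".join(
        (key.sender, key.receiver, key.ligand_complex, key.receptor_complex)
    )


def label_to_key(label: str) -> InteractionKey:
    parts = label.split("|")
    if len(parts) != 4:
        raise ValueError(f"not a serialized interaction key: {label!r}")
    sender, receiver, lig, rec = parts
    return InteractionKey(sender, receiver, tuple(lig.split("_")), tuple(rec.split("_")))


def compute_mean_rank(method_ranks: Mapping[str, float]) -> float:
    """Arithmetic mean of per-method ranks over the methods present.

    Methods that did not score the interaction simply do not contribute;
    an empty map is an error because the mean is undefined.
    """
    if not method_ranks:
        raise ValueError("method_ranks is empty; mean rank undefined")
    vals = list(method_ranks.values())
    if any(v < 1 for v in vals):
        raise ValueError("method ranks must be >= 1")
    return float(sum(vals)) / len(vals)


def interaction_score(mean_rank: float) -> float:
    """Display score 1 / ln(mean rank): large = strong interaction.

    Strictly decreasing on (1, inf); undefined at mean_rank <= 1 where the
    log is nonpositive.
    """
    if mean_rank <= 1:
        raise ValueError(f"interaction_score requires mean_rank > 1, got {mean_rank}")
    return 1.0 / math.log(mean_rank)


@dataclass(frozen=True)
class RankedInteraction:
    key: InteractionKey
    method_ranks: Mapping[str, float]
    aggregate_rank: float
    mean_rank: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (0 < self.aggregate_rank <= 1):
            raise ValueError(
                f"aggregate_rank must lie in (0, 1], got {self.aggregate_rank}"
            )
        mr = compute_mean_rank(self.method_ranks)
        if math.isnan(self.mean_rank):
            object.__setattr__(self, "mean_rank", mr)
        elif not math.isclose(self.mean_rank, mr, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"mean_rank {self.mean_rank} inconsistent with method ranks (mean {mr})"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    patient_id: str
    timepoint: str
    response: str

    def __post_init__(self) -> None:
        if self.timepoint not in _TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {sorted(_TIMEPOINTS)}")
        if self.response not in _RESPONSES:
            raise ValueError(f"response must be one of {sorted(_RESPONSES)}")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_interaction_tables(
    paths: Sequence[str | Path],
) -> dict[str, list[RankedInteraction]]:
    """Read delimited interaction tables into per-sample record lists.

    Any column named ``<method>_rank`` (other than ``aggregate_rank`` and
    ``mean_rank``) is treated as a method rank.  Duplicate keys within a
    sample and out-of-range values raise :class:`ParseError` naming the file
    and data line.
    """
    records: dict[str, list[RankedInteraction]] = {}
    seen: dict[str, set[InteractionKey]] = {}
    for raw in paths:
        path = Path(raw)
        try:
            frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed delimiter/quoting
            raise ParseError(f"{path}: unreadable table ({exc})") from exc
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"{path}: missing required column(s) {missing}")
        method_cols = [
            c
            for c in frame.columns
            if c.endswith("_rank") and c not in ("aggregate_rank", "mean_rank")
        ]
        if not method_cols:
            raise ParseError(f"{path}: no per-method rank column (expected '<method>_rank')")
        for i, row in enumerate(frame.itertuples(index=False), start=2):
            row = row._asdict()
            where = f"{path}:{i}"
            key = InteractionKey(
                row["source"],
                row["target"],
                tuple(str(row["ligand_complex"]).split("_")),
                tuple(str(row["receptor_complex"]).split("_")),
            )
            method_ranks: dict[str, float] = {}
            for col in method_cols:
                value = row[col]
                if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
                    continue
                try:
                    method_ranks[col[: -len("_rank")]] = float(value)
                except ValueError:
                    raise ParseError(f"{where}: non-numeric rank {value!r} in {col}") from None
            try:
                agg = float(row["aggregate_rank"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{where}: non-numeric aggregate_rank {row['aggregate_rank']!r}"
                ) from None
            sample = str(row["sample_id"])
            try:
                rec = RankedInteraction(key, method_ranks, agg)
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from None
            bucket = seen.setdefault(sample, set())
            if key in bucket:
                raise ParseError(f"{where}: duplicate interaction {key_to_label(key)} in sample {sample}")
            bucket.add(key)
            records.setdefault(sample, []).append(rec)
        # header-only file: still register declared samples as empty? A file
        # carries its samples in rows, so nothing to add -- empty is fine.
    return records


def write_interaction_table(
    records: Mapping[str, Sequence[RankedInteraction]],
    path: str | Path,
    methods: Sequence[str] = CANONICAL_METHODS,
) -> None:
    """Write per-sample records as one delimited table (inverse of the reader)."""
    path = Path(path)
    rows = []
    for sample in records:
        for rec in records[sample]:
            row = {
                "sample_id": sample,
                "source": rec.key.sender,
                "target": rec.key.receiver,
                "ligand_complex": rec.key.ligand_complex,
                "receptor_complex": rec.key.receptor_complex,
            }
            for m in methods:
                if m in rec.method_ranks:
                    row[f"{m}_rank"] = rec.method_ranks[m]
            for m in rec.method_ranks:
                if m not in methods:
                    row[f"{m}_rank"] = rec.method_ranks[m]
            row["aggregate_rank"] = rec.aggregate_rank
            rows.append(row)
    cols = list(_REQUIRED_COLUMNS[:5]) + [f"{m}_rank" for m in methods] + ["aggregate_rank"]
    frame = pd.DataFrame(rows)
    for c in cols:
        if c not in frame.columns:
            frame[c] = np.nan
    extra = [c for c in frame.columns if c not in cols]
    frame = frame[cols[:5] + sorted(set(cols[5:-1]) | set(extra)) + ["aggregate_rank"]]
    frame.to_csv(path, sep=_sep_for(path), index=False)


def read_metadata(path: str | Path) -> dict[str, SampleAnnotation]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ("sample_id", "patient_id", "timepoint", "response")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out: dict[str, SampleAnnotation] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            ann = SampleAnnotation(row.sample_id, row.patient_id, row.timepoint, row.response)
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
        if ann.sample_id in out:
            raise ParseError(f"{path}:{i}: duplicate sample_id {ann.sample_id}")
        out[ann.sample_id] = ann
    return out


def write_metadata(annotations: Mapping[str, SampleAnnotation], path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "patient_id": a.patient_id,
                "timepoint": a.timepoint,
                "response": a.response,
            }
            for a in annotations.values()
        ]
    )
    frame.to_csv(path, sep=_sep_for(path), index=False)


def build_rank_matrix(
    records: Mapping[str, Sequence[RankedInteraction]],
    annotations: Mapping[str, SampleAnnotation],
) -> pd.DataFrame:
    """Assemble the sample x interaction mean-rank matrix.

    Columns are serialized interaction keys in lexicographic order; a cell is
    NaN wherever the sample's table lacks that interaction.  Every sample
    must carry an annotation, so downstream group comparisons never meet an
    unlabelled row.
    """
    unannotated = [s for s in records if s not in annotations]
    if unannotated:
        raise KeyError(f"samples without metadata annotation: {sorted(unannotated)}")
    samples = sorted(records)
    labels = sorted({key_to_label(r.key) for recs in records.values() for r in recs})
    matrix = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample_id"), columns=labels)
    for sample in samples:
        for rec in records[sample]:
            matrix.loc[sample, key_to_label(rec.key)] = rec.mean_rank
    return matrix
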