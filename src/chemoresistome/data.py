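"""Validated in-memory data model shared by every analysis stage.

The containers are deliberately thin: a count matrix is genes x samples
integers, the sample table maps samples to (patient, timepoint) where the
timepoint is one of the matched-triplet states (adjacent normal epithelium,
pretreatment biopsy, posttreatment residual tumor), and the patient table
carries the clinical annotations used downstream (Miller-Payne response
grade, RCB class, subtype, recurrence-free survival).

Gene identifiers are opaque strings; no identifier mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

TIMEPOINTS = ("normal", "pre", "post")
SUBTYPES = ("TNBC", "HR+", "TP")
RCB_CLASSES = ("RCB-I", "RCB-II", "RCB-III")


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountMatrix:
    """Raw integer RNA-seq counts, genes in rows, samples in columns."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = _check_unique(map(str, self.genes), "gene")
        self.samples = _check_unique(map(str, self.samples), "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                raise ValidationError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        idx = pd.Index(self.genes).get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return CountMatrix([self.genes[i] for i in idx], list(self.samples), self.counts[idx])


@dataclass
class SampleTable:
    """Sample -> (patient, timepoint) map with optional tumor cellularity."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "timepoint")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        _check_unique(df["sample_id"].astype(str), "sample")
        bad = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise ValidationError(f"invalid timepoint values: {sorted(bad)}")
        dup = df.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            pair = df.loc[dup, ["patient_id", "timepoint"]].iloc[0]
            raise ValidationError(
                f"(patient, timepoint) appears more than once: "
                f"({pair['patient_id']}, {pair['timepoint']})"
            )
        if "cellularity" in df.columns:
            cell = pd.to_numeric(df["cellularity"], errors="coerce")
            ok = cell.isna() | ((cell >= 0) & (cell <= 1))
            if not ok.all():
                raise ValidationError("cellularity must be in [0, 1]")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"].astype(str))

    def patients(self) -> list[str]:
        return sorted(set(self.df["patient_id"].astype(str)))


@dataclass
class PatientTable:
    """Per-patient clinical annotations (MP grade, subtype, survival)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("patient_id", "mp_score"):
            if col not in df.columns:
                raise ValidationError(f"patient table missing column {col!r}")
        _check_unique(df["patient_id"].astype(str), "patient")
        mp = pd.to_numeric(df["mp_score"], errors="coerce")
        if mp.isna().any() or not mp.isin([1, 2, 3, 4, 5]).all():
            raise ValidationError("mp_score must be an integer grade in 1..5")
        df["mp_score"] = mp.astype(int)
        if "rcb_class" in df.columns:
            bad = set(df["rcb_class"].dropna()) - set(RCB_CLASSES)
            if bad:
                raise ValidationError(f"invalid RCB class values: {sorted(bad)}")
        if "subtype" in df.columns:
            bad = set(df["subtype"].dropna()) - set(SUBTYPES)
            if bad:
                raise ValidationError(f"invalid subtype values: {sorted(bad)}")
        if "rfs_years" in df.columns:
            rfs = pd.to_numeric(df["rfs_years"], errors="coerce")
            if ((rfs < 0) & rfs.notna()).any():
                raise ValidationError("rfs_years must be non-negative")
        self.df = df.reset_index(drop=True)

    def mp_map(self) -> dict[str, int]:
        return dict(zip(self.df["patient_id"].astype(str), self.df["mp_score"]))

    def subtype_map(self) -> dict[str, str]:
        if "subtype" not in self.df.columns:
            return {}
        return dict(zip(self.df["patient_id"].astype(str), self.df["subtype"]))


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        # collapse duplicates, preserve first-seen order
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g), None)
        if not seen:
            raise ValidationError(f"gene set {self.name!r} is empty")
        self.genes = tuple(seen)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), e.g. parsed from a GMT file."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"gene set key {name!r} != set name {gs.name!r}")

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def intersect_universe(self, universe: Iterable[str]) -> dict[str, tuple[str, ...]]:
        """Member genes restricted to ``universe``; empty sets dropped."""
        uni = set(universe)
        out = {}
        for gs in self:
            kept = tuple(g for g in gs.genes if g in uni)
            if kept:
                out[gs.name] = kept
        return out


class Triplet(NamedTuple):
    patient_id: str
    normal: str
    pre: str
    post: str

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.normal, self.pre, self.post)


class TripletIndex(NamedTuple):
    triplets: list[Triplet]
    incomplete: dict[str, list[str]]  # patient -> missing timepoints


def build_triplets(counts: CountMatrix, samples: SampleTable) -> TripletIndex:
    """Matched normal/pre/post triplets for patients with all three samples.

    Patients missing any timepoint (or whose sample is absent from the count
    matrix) are not fatal: they are returned in the ``incomplete`` side report,
    mirroring the enrollment-to-analysis funnel of a real cohort.
    Triplets are sorted by patient id for reproducible downstream iteration.
    """
    present = set(counts.samples)
    by_patient: dict[str, dict[str, str]] = {}
    for _, row in samples.df.iterrows():
        sid = str(row["sample_id"])
        if sid not in present:
            continue
        by_patient.setdefault(str(row["patient_id"]), {})[row["timepoint"]] = sid
    all_patients = sorted(set(samples.df["patient_id"].astype(str)))
    triplets: list[Triplet] = []
    incomplete: dict[str, list[str]] = {}
    for pid in all_patients:
        tps = by_patient.get(pid, {})
        missing = [t for t in TIMEPOINTS if t not in tps]
        if missing:
            incomplete[pid] = missing
        else:
            triplets.append(Triplet(pid, tps["normal"], tps["pre"], tps["post"]))
    return TripletIndex(triplets, incomplete)


def triplet_value_array(
    values: pd.DataFrame, triplets: list[Triplet]
) -> np.ndarray:
    """Stack per-triplet (normal, pre, post) columns: (n_genes, n_triplets, 3)."""
    cols = []
    for t in triplets:
        cols.append(values[list(t.sample_ids)].to_numpy())
    if not cols:
        return np.empty((len(values), 0, 3))
    return np.stack(cols, axis=1)
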