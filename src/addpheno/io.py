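"""Cohort tables, split archives and label files.

A cohort is a table of per-animal summary counts from the three behavioural
screens of the 3-criteria addiction model: responding under a progressive
ratio schedule (motivation), responding during signalled drug unavailability
(drug seeking), and responding maintained under punishment (compulsivity).
Readers take an explicit column mapping because deposited files do not share
a header convention; nothing is inferred.
"""

from __future__ import annotations

import io as _stdio
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError, ParseError

#: Canonical feature order used by every matrix in the package:
#: column 0 motivation, column 1 seeking, column 2 punished responding.
FEATURE_FIELDS = ("motivation", "seeking_during_no_drug", "punished_responding")

ROLES = ("vulnerable", "resilient")

#: Default column mapping: profile field -> file column name.
DEFAULT_COLUMN_MAP = {
    "animal_id": "animal_id",
    "motivation": "motivation",
    "seeking_during_no_drug": "seeking",
    "punished_responding": "punished",
    "crit_label": "crit",
}


@dataclass(frozen=True)
class BehaviorProfile:
    """One animal's three raw instrumental-response measurements."""

    animal_id: str
    motivation: float
    seeking_during_no_drug: float
    punished_responding: float
    crit_label: int | None = None

    def __post_init__(self) -> None:
        for name in FEATURE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise IntegrityError(f"{name} of animal {self.animal_id!r} is not finite")
            if v < 0:
                raise IntegrityError(f"{name} of animal {self.animal_id!r} is negative")
        if self.crit_label is not None and self.crit_label not in (0, 1, 2, 3):
            raise IntegrityError(
                f"crit_label of animal {self.animal_id!r} must be in 0..3, got {self.crit_label}"
            )

    @property
    def features(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_FIELDS], dtype=float)


@dataclass
class Cohort:
    """An ordered collection of behaviour profiles with optional crit labels.

    ``drug`` tags the substance the cohort was screened with; ``source`` is
    free-text provenance.
    """

    profiles: list[BehaviorProfile]
    drug: str = "other"
    source: str = ""

    def __post_init__(self) -> None:
        ids = [p.animal_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise IntegrityError(f"duplicate animal_id {dup!r} in cohort")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[BehaviorProfile]:
        return iter(self.profiles)

    @property
    def animal_ids(self) -> list[str]:
        return [p.animal_id for p in self.profiles]

    @property
    def features(self) -> np.ndarray:
        """n x 3 float matrix in canonical feature order."""
        if not self.profiles:
            return np.empty((0, 3), dtype=float)
        return np.vstack([p.features for p in self.profiles])

    @property
    def crit_labels(self) -> np.ndarray:
        """Per-animal crit group as float array with NaN where unknown."""
        return np.array(
            [np.nan if p.crit_label is None else p.crit_label for p in self.profiles],
            dtype=float,
        )

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort([self.profiles[i] for i in indices], drug=self.drug, source=self.source)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "animal_id": self.animal_ids,
            "motivation": [p.motivation for p in self.profiles],
            "seeking": [p.seeking_during_no_drug for p in self.profiles],
            "punished": [p.punished_responding for p in self.profiles],
        }
        df = pd.DataFrame(rows)
        if any(p.crit_label is not None for p in self.profiles):
            df["crit"] = [p.crit_label for p in self.profiles]
        return df


@dataclass
class SplitArchive:
    """Paired training/test cohorts from repeated random splits."""

    pairs: list[tuple[Cohort, Cohort]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate(self, parent: Cohort | None = None) -> None:
        for i, (tr, te) in enumerate(self.pairs):
            overlap = set(tr.animal_ids) & set(te.animal_ids)
            if overlap:
                raise IntegrityError(
                    f"pair {i}: animal_ids shared between training and test: {sorted(overlap)}"
                )
            if parent is not None:
                union = set(tr.animal_ids) | set(te.animal_ids)
                if union != set(parent.animal_ids):
                    raise IntegrityError(f"pair {i}: union does not equal the parent cohort")

    def flatten(self) -> list[Cohort]:
        """All training sets followed by all test sets (2 * n_pairs cohorts)."""
        return [p[0] for p in self.pairs] + [p[1] for p in self.pairs]


def _parse_measurement(value, column: str, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {value!r} in column {column!r} at data row {row}"
        ) from None
    if np.isnan(out):
        raise ParseError(f"missing/NaN value in column {column!r} at data row {row}")
    return out


def _frame_to_cohort(
    df: pd.DataFrame, column_map: Mapping[str, str], drug: str, source: str
) -> Cohort:
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    required = ["animal_id", *FEATURE_FIELDS]
    for fld in required:
        col = cmap[fld]
        if col not in df.columns:
            raise FormatError(f"required column {col!r} (field {fld!r}) missing from file")
    crit_col = cmap.get("crit_label")
    has_crit = crit_col is not None and crit_col in df.columns

    profiles = []
    for row_idx, (_, row) in enumerate(df.iterrows()):
        values = {
            fld: _parse_measurement(row[cmap[fld]], cmap[fld], row_idx)
            for fld in FEATURE_FIELDS
        }
        crit = None
        if has_crit and not pd.isna(row[crit_col]):
            crit_f = _parse_measurement(row[crit_col], crit_col, row_idx)
            if crit_f != int(crit_f):
                raise ParseError(f"non-integer crit value {crit_f} at data row {row_idx}")
            crit = int(crit_f)
        profiles.append(
            BehaviorProfile(animal_id=str(row[cmap["animal_id"]]), crit_label=crit, **values)
        )
    return Cohort(profiles, drug=drug, source=source)


def read_cohort(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    drug: str = "other",
    sheet: int | str = 0,
) -> Cohort:
    """Read a cohort table from CSV or XLSX.

    ``column_map`` maps profile fields (``animal_id``, ``motivation``,
    ``seeking_during_no_drug``, ``punished_responding``, optionally
    ``crit_label``) to the column names in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        raise FormatError(f"unknown format {fmt!r}; expected 'csv' or 'xlsx'")
    return _frame_to_cohort(df, column_map or {}, drug=drug, source=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV using the canonical header; round-trips losslessly."""
    cohort.to_frame().to_csv(path, index=False)


def write_labels(cohort: Cohort, labels: Sequence[str], path: str | Path) -> None:
    """Write per-animal vulnerable/resilient labels next to ids (and crit when known)."""
    labels = list(labels)
    if len(labels) != len(cohort):
        raise IntegrityError(
            f"{len(labels)} labels for {len(cohort)} animals"
        )
    bad = [l for l in labels if l not in ROLES]
    if bad:
        raise IntegrityError(f"labels outside {ROLES}: {sorted(set(bad))}")
    df = pd.DataFrame({"animal_id": cohort.animal_ids, "label": labels})
    if any(p.crit_label is not None for p in cohort.profiles):
        df["crit"] = [p.crit_label for p in cohort.profiles]
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal_id", "label"):
        if col not in df.columns:
            raise FormatError(f"label file missing column {col!r}")
    bad = set(df["label"]) - set(ROLES)
    if bad:
        raise IntegrityError(f"labels outside {ROLES}: {sorted(bad)}")
    return df


_TRAIN_RE = re.compile(r"train", re.IGNORECASE)
_TEST_RE = re.compile(r"test", re.IGNORECASE)
_INDEX_RE = re.compile(r"(\d+)")


def _pair_key(name: str) -> tuple[str, str]:
    """Classify a member file name as (kind, pair index)."""
    stem = Path(name).stem
    if _TRAIN_RE.search(stem):
        kind = "train"
    elif _TEST_RE.search(stem):
        kind = "test"
    else:
        raise FormatError(f"cannot classify {name!r} as a training or test set file")
    m = _INDEX_RE.findall(stem)
    if not m:
        raise FormatError(f"no pair index found in file name {name!r}")
    return kind, m[-1]


def read_split_archive(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    drug: str = "other",
) -> SplitArchive:
    """Reconstruct training/test pairs from a directory or zip of CSV files.

    Files are paired by the last integer in their names; a file is a training
    set if its name contains "train", a test set if it contains "test".
    """
    path = Path(path)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    if path.is_dir():
        members = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
        for member in members:
            tables[_pair_key(member.name)] = pd.read_csv(member)
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if not name.lower().endswith(".csv") or name.endswith("/"):
                    continue
                with zf.open(name) as fh:
                    tables[_pair_key(name)] = pd.read_csv(_stdio.TextIOWrapper(fh, "utf-8"))
    else:
        raise FormatError(f"{path} is neither a directory nor a zip archive")

    indices = sorted({idx for _, idx in tables}, key=lambda s: (len(s), s))
    pairs = []
    for idx in indices:
        if ("train", idx) not in tables or ("test", idx) not in tables:
            raise FormatError(f"unmatched training/test file for pair index {idx!r}")
        tr = _frame_to_cohort(tables[("train", idx)], column_map or {}, drug, f"{path}:train{idx}")
        te = _frame_to_cohort(tables[("test", idx)], column_map or {}, drug, f"{path}:test{idx}")
        pairs.append((tr, te))
    archive = SplitArchive(pairs)
    archive.validate()
    return archive


def write_split_archive(archive: SplitArchive, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (tr, te) in enumerate(archive.pairs, start=1):
        write_cohort(tr, directory / f"training_set_{i}.csv")
        write_cohort(te, directory / f"test_set_{i}.csv")


def cohort_from_arrays(
    features: np.ndarray,
    animal_ids: Sequence[str] | None = None,
    crit_labels: Sequence[int | None] | None = None,
    drug: str = "other",
    source: str = "",
) -> Cohort:
    """Build a cohort from an n x 3 matrix in canonical feature order."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if animal_ids is None:
        animal_ids = [f"animal_{i:04d}" for i in range(n)]
    profiles = [
        BehaviorProfile(
            animal_id=str(animal_ids[i]),
            motivation=features[i, 0],
            seeking_during_no_drug=features[i, 1],
            punished_responding=features[i, 2],
            crit_label=None if crit_labels is None else crit_labels[i],
        )
        for i in range(n)
    ]
    return Cohort(profiles, drug=drug, source=source)
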