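"""Domain containers for engraftment studies.

An engraftment study couples an integer ASV count table (samples x ASVs)
with per-sample design metadata: which human donor the sample traces back
to, whether it is a donor inoculum aliquot or a recipient-animal fecal
sample, and — for fecal samples — the animal identity and day
post-inoculation. All containers are identifier-keyed: results never
depend on the order in which samples or ASVs appear in input files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyTable",
    "StudyDesign",
    "ValidationReport",
    "HOSTS",
    "SAMPLE_TYPES",
    "RANKS",
    "filter_samples_by_depth",
    "relative_abundance",
    "validate_study",
]

HOSTS = ("human_donor", "mouse", "piglet")
SAMPLE_TYPES = ("inoculum", "fecal")
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Sampling schedule used throughout: days post-inoculation at which
#: recipient-animal fecal samples are collected.
DEFAULT_SCHEDULE = (2, 7, 14, 21, 28, 35, 40)


@dataclass(frozen=True)
class StudyDesign:
    """Tunable thresholds of the engraftment analysis.

    Parameters
    ----------
    schedule
        Ordered fecal sampling days post-inoculation.
    min_sample_depth
        Samples with fewer total reads are removed; the comparison is
        strict ("less than"), so a sample at exactly this depth survives.
    persistence_min_timepoints
        Minimum number of qualifying days (out of the schedule) for an
        ASV to count as a persistent colonizer, and for a persistent
        colonizer to count as maintaining a donor-like abundance.
    persistence_fraction
        An ASV qualifies on a day only when detected in strictly more
        than this fraction of the animals sampled that day.
    detection_min_count
        Reads required to call an ASV present in a sample.
    alpha
        Significance level for differential-abundance calls.
    """

    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    min_sample_depth: int = 10_500
    persistence_min_timepoints: int = 4
    persistence_fraction: float = 0.5
    detection_min_count: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.schedule) != len(set(self.schedule)):
            raise ValueError("schedule days must be unique")
        if self.persistence_min_timepoints > len(self.schedule):
            raise ValueError(
                "persistence_min_timepoints exceeds the number of scheduled days"
            )
        if not 0 < self.persistence_fraction < 1:
            raise ValueError("persistence_fraction must lie strictly in (0, 1)")
        if self.detection_min_count < 1:
            raise ValueError("detection_min_count must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")

    def replace(self, **kwargs) -> "StudyDesign":
        return dataclasses.replace(self, **kwargs)


class FeatureTable:
    """Immutable integer count matrix, samples x ASVs, identifier-keyed.

    Wraps a :class:`pandas.DataFrame` whose index holds sample
    identifiers and whose columns hold ASV identifiers. Counts are
    validated to be non-negative integers; fractional input is rejected
    rather than rounded because detection calls and count-based testing
    downstream assume true read counts.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV identifiers: {dups}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if np.isnan(values).any() or frac.any():
                i, j = np.argwhere(np.isnan(values) | frac)[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{counts.index[i]!r}, ASV {counts.columns[j]!r}"
                )
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[i]!r}, "
                f"ASV {counts.columns[j]!r}"
            )
        self._counts = counts.astype(np.int64)
        self._counts.index = self._counts.index.astype(str)
        self._counts.columns = self._counts.columns.astype(str)
        self._counts.index.name = "sample_id"
        self._counts.columns.name = "asv_id"

    @property
    def counts(self) -> pd.DataFrame:
        """Counts as a DataFrame (copy; the table itself is immutable)."""
        return self._counts.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    def depths(self) -> pd.Series:
        """Total read count per sample."""
        return self._counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self._counts.loc[list(sample_ids)])

    def select_asvs(self, asv_ids) -> "FeatureTable":
        return FeatureTable(self._counts[list(asv_ids)])

    def dataframe(self) -> pd.DataFrame:
        return self._counts.copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self._counts.equals(other._counts)

    def __repr__(self) -> str:
        n, m = self._counts.shape
        return f"FeatureTable({n} samples x {m} ASVs)"

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        """Stack tables sample-wise; missing ASVs are zero-filled."""
        frames = [t._counts for t in tables]
        merged = pd.concat(frames, axis=0).fillna(0)
        return FeatureTable(merged)


REQUIRED_METADATA_COLUMNS = (
    "donor_id",
    "host",
    "sample_type",
    "subject_id",
    "day_post_inoculation",
)


class SampleMetadata:
    """Per-sample design annotations, indexed by sample identifier.

    Inoculum samples belong to the human donor and carry no animal or
    day; fecal samples belong to a recipient host species and carry
    both. Extra columns pass through untouched.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in metadata: {dups}")
        df.index = df.index.astype(str)
        df["day_post_inoculation"] = pd.array(
            [
                None if (v is None or (isinstance(v, str) and v == "") or pd.isna(v))
                else int(v)
                for v in df["day_post_inoculation"]
            ],
            dtype="Int64",
        )
        df["subject_id"] = df["subject_id"].where(
            ~df["subject_id"].isin(["", None]) & df["subject_id"].notna(), None
        )
        self._validate_rows(df)
        self._data = df

    @staticmethod
    def _validate_rows(df: pd.DataFrame) -> None:
        bad_host = set(df["host"]) - set(HOSTS)
        if bad_host:
            raise ValueError(f"unknown host values: {sorted(bad_host)}")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValueError(f"unknown sample_type values: {sorted(bad_type)}")
        inoc = df["sample_type"] == "inoculum"
        if (df.loc[inoc, "host"] != "human_donor").any():
            raise ValueError("inoculum samples must have host=human_donor")
        if df.loc[inoc, "day_post_inoculation"].notna().any():
            raise ValueError("inoculum samples must not carry a sampling day")
        fecal = df["sample_type"] == "fecal"
        if (df.loc[fecal, "host"] == "human_donor").any():
            raise ValueError("fecal samples must belong to a recipient host")
        if df.loc[fecal, "subject_id"].isna().any():
            raise ValueError("fecal samples require a subject_id")
        if df.loc[fecal, "day_post_inoculation"].isna().any():
            raise ValueError("fecal samples require day_post_inoculation")

    @property
    def data(self) -> pd.DataFrame:
        return self._data.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    def donors(self) -> list[str]:
        return sorted(self._data["donor_id"].unique())

    def hosts(self) -> list[str]:
        fecal = self._data[self._data["sample_type"] == "fecal"]
        return sorted(fecal["host"].unique())

    def inoculum_samples(self, donor_id: str) -> list[str]:
        df = self._data
        mask = (df["donor_id"] == donor_id) & (df["sample_type"] == "inoculum")
        return list(df.index[mask])

    def fecal_samples(
        self, donor_id: str | None = None, host: str | None = None,
        day: int | None = None,
    ) -> list[str]:
        df = self._data
        mask = df["sample_type"] == "fecal"
        if donor_id is not None:
            mask &= df["donor_id"] == donor_id
        if host is not None:
            mask &= df["host"] == host
        if day is not None:
            mask &= df["day_post_inoculation"] == day
        return list(df.index[mask])

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self._data.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self._data.equals(other._data)


class TaxonomyTable:
    """Ranked lineages per ASV (domain through species).

    Lower ranks may be empty, but an empty rank never has a non-empty
    rank below it (hierarchy is prefix-shaped).
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if df.index.name != "asv_id":
            if "asv_id" in df.columns:
                df = df.set_index("asv_id")
            else:
                df.index.name = "asv_id"
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        if df.index.has_duplicates:
            raise ValueError("duplicate ASV identifiers in taxonomy")
        df = df[list(RANKS)].fillna("").astype(str)
        arr = df.to_numpy()
        nonempty = arr != ""
        for row, asv in zip(nonempty, df.index):
            seen_empty = False
            for flag in row:
                if not flag:
                    seen_empty = True
                elif seen_empty:
                    raise ValueError(
                        f"taxonomy for {asv!r} has a named rank below an empty one"
                    )
        df.index = df.index.astype(str)
        self._data = df

    @property
    def data(self) -> pd.DataFrame:
        return self._data.copy()

    @property
    def asv_ids(self) -> list[str]:
        return list(self._data.index)

    def rank(self, rank: str, asv_ids=None, unclassified: str = "unclassified") -> pd.Series:
        """Rank labels per ASV; empty or missing assignments become
        ``unclassified``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
        if asv_ids is None:
            series = self._data[rank]
        else:
            asv_ids = list(asv_ids)
            series = self._data[rank].reindex(asv_ids).fillna("")
        return series.replace("", unclassified)


@dataclass
class ValidationReport:
    """Diagnostics from cross-checking a table against its metadata."""

    samples_missing_metadata: list[str] = field(default_factory=list)
    metadata_without_samples: list[str] = field(default_factory=list)
    donors_without_inoculum: list[str] = field(default_factory=list)
    off_schedule_samples: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.samples_missing_metadata
            or self.metadata_without_samples
            or self.donors_without_inoculum
            or self.off_schedule_samples
        )


def filter_samples_by_depth(table: FeatureTable, min_depth: int) -> FeatureTable:
    """Drop samples with fewer than ``min_depth`` total reads.

    Strict comparison: a sample at exactly ``min_depth`` is retained.
    The ASV set is unchanged; an empty result is permitted.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depths = table.depths()
    keep = depths.index[depths >= min_depth]
    return table.select_samples(keep)


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions (each row sums to 1).

    Raises for zero-depth samples: proportions are undefined there, and
    such samples should be removed by the depth filter first.
    """
    depths = table.depths()
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise ValueError(f"zero-depth samples have no relative abundances: {zero}")
    counts = table.dataframe()
    return counts.div(depths, axis=0)


def validate_study(
    table: FeatureTable,
    metadata: SampleMetadata,
    design: StudyDesign | None = None,
) -> ValidationReport:
    """Diagnostic cross-check of a study: never raises, reports problems."""
    design = design or StudyDesign()
    table_ids = set(table.sample_ids)
    meta_ids = set(metadata.sample_ids)
    report = ValidationReport(
        samples_missing_metadata=sorted(table_ids - meta_ids),
        metadata_without_samples=sorted(meta_ids - table_ids),
    )
    df = metadata.data
    for donor in sorted(df["donor_id"].unique()):
        inoc = metadata.inoculum_samples(donor)
        if not [s for s in inoc if s in table_ids]:
            report.donors_without_inoculum.append(donor)
    fecal = df[df["sample_type"] == "fecal"]
    off = fecal.index[~fecal["day_post_inoculation"].isin(design.schedule)]
    report.off_schedule_samples = sorted(off)
    return report
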