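"""Colonization-outcome classification of core donor ASVs.

Each core donor ASV is scored per recipient host group on a three-rung
ladder:

* **non_colonizer** — never detected in any fecal sample of the group;
* **colonizer** — detected in at least one fecal sample;
* **persistent_colonizer** — detected in strictly more than half of the
  sampled animals on at least 4 of the 7 scheduled days.

The persistence denominator on a given day is the number of animals that
actually contributed a sample that day, so animal deaths shrink the
denominator rather than counting as non-detections (an enrolled-animal
denominator is available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import IntEnum

import numpy as np
import pandas as pd

from .core import CoreSet
from .model import FeatureTable, SampleMetadata, StudyDesign, TaxonomyTable

__all__ = [
    "Status",
    "ColonizationCall",
    "EngraftmentSummary",
    "CrossModelContingency",
    "detect_presence",
    "classify_colonizers",
    "classify_persistent",
    "summarize_engraftment",
    "cross_model_contingency",
    "rollup_by_taxon",
    "union_rollup",
    "round_half_away",
    "percentage",
    "calls_to_frame",
]


class Status(IntEnum):
    """Colonization ladder; comparisons follow the ladder order."""

    non_colonizer = 0
    colonizer = 1
    persistent_colonizer = 2

    def __str__(self) -> str:  # TSV-friendly
        return self.name


@dataclass(frozen=True)
class ColonizationCall:
    """Outcome for one (donor, host, ASV) triple."""

    donor_id: str
    host: str
    asv_id: str
    status: Status
    n_majority_timepoints: int
    day_detection_fractions: tuple[float, ...]


@dataclass(frozen=True)
class EngraftmentSummary:
    """Per donor x host roll-up mirroring the study's summary table."""

    donor_id: str
    host: str
    n_core: int
    n_colonizers: int
    pct_colonizers: float
    n_persistent: int
    pct_persistent: float
    mean_fecal_depth: int


@dataclass(frozen=True)
class CrossModelContingency:
    """2x2 partition of one donor's core by colonization in two hosts."""

    donor_id: str
    host_a: str
    host_b: str
    basis: Status
    both_hosts: int
    host_a_only: int
    host_b_only: int
    neither: int

    @property
    def n_core(self) -> int:
        return self.both_hosts + self.host_a_only + self.host_b_only + self.neither


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """100*count/total, rounded half-away-from-zero."""
    if total <= 0:
        raise ValueError("percentage needs a positive denominator")
    return round_half_away(100.0 * count / total, ndigits)


def detect_presence(table: FeatureTable, design: StudyDesign | None = None) -> pd.DataFrame:
    """Boolean samples x ASVs matrix: count >= detection_min_count."""
    design = design or StudyDesign()
    return table.dataframe() >= design.detection_min_count


def _fecal_presence(
    presence: pd.DataFrame,
    metadata: SampleMetadata,
    donor_id: str,
    host: str,
) -> pd.DataFrame:
    samples = [
        s for s in metadata.fecal_samples(donor_id=donor_id, host=host)
        if s in presence.index
    ]
    if not samples:
        raise ValueError(f"no fecal samples for donor {donor_id!r}, host {host!r}")
    return presence.loc[samples]


def classify_colonizers(
    presence: pd.DataFrame,
    metadata: SampleMetadata,
    donor_id: str,
    host: str,
    core: CoreSet,
) -> list[ColonizationCall]:
    """Colonizer = detected in >= 1 fecal sample of the donor x host group.

    Only the colonizer rung is assessed; persistence fields are zeroed.
    Use :func:`classify_persistent` for the full ladder.
    """
    fecal = _fecal_presence(presence, metadata, donor_id, host)
    calls = []
    for asv in core.asv_ids:
        detected = bool(fecal[asv].any()) if asv in fecal.columns else False
        calls.append(
            ColonizationCall(
                donor_id=donor_id,
                host=host,
                asv_id=asv,
                status=Status.colonizer if detected else Status.non_colonizer,
                n_majority_timepoints=0,
                day_detection_fractions=(),
            )
        )
    return calls


def classify_persistent(
    presence: pd.DataFrame,
    metadata: SampleMetadata,
    donor_id: str,
    host: str,
    core: CoreSet,
    design: StudyDesign | None = None,
    denominator: str = "sampled",
) -> list[ColonizationCall]:
    """Full ladder classification including persistence.

    Per scheduled day, an ASV's detection fraction is (animals with a
    detection that day) / (animals with a sample that day); the day
    qualifies when the fraction strictly exceeds ``persistence_fraction``.
    An ASV is persistent when qualifying days reach
    ``persistence_min_timepoints``. Days without samples contribute
    nothing, which makes the rule conservative under missingness.

    ``denominator='enrolled'`` divides by all animals ever seen for the
    group instead (sensitivity-analysis mode).
    """
    design = design or StudyDesign()
    if denominator not in ("sampled", "enrolled"):
        raise ValueError("denominator must be 'sampled' or 'enrolled'")
    fecal = _fecal_presence(presence, metadata, donor_id, host)
    meta = metadata.data.loc[fecal.index]
    enrolled = meta["subject_id"].nunique()

    # animal-level detection per day: an animal detects the ASV on a day
    # if any of its samples that day does
    day_frames: list[tuple[int, pd.DataFrame, int]] = []
    for day in design.schedule:
        day_samples = meta.index[meta["day_post_inoculation"] == day]
        if len(day_samples) == 0:
            continue
        by_animal = fecal.loc[day_samples].groupby(meta.loc[day_samples, "subject_id"]).any()
        denom = len(by_animal) if denominator == "sampled" else enrolled
        day_frames.append((day, by_animal, denom))

    calls = []
    core_asvs = list(core.asv_ids)
    any_detection = fecal[ [a for a in core_asvs if a in fecal.columns] ].any(axis=0)
    for asv in core_asvs:
        fractions = []
        qualifying = 0
        for _day, by_animal, denom in day_frames:
            frac = float(by_animal[asv].sum() / denom) if asv in by_animal.columns else 0.0
            fractions.append(frac)
            if frac > design.persistence_fraction:
                qualifying += 1
        detected = bool(any_detection.get(asv, False))
        if qualifying >= design.persistence_min_timepoints:
            status = Status.persistent_colonizer
        elif detected:
            status = Status.colonizer
        else:
            status = Status.non_colonizer
        calls.append(
            ColonizationCall(
                donor_id=donor_id,
                host=host,
                asv_id=asv,
                status=status,
                n_majority_timepoints=qualifying,
                day_detection_fractions=tuple(fractions),
            )
        )
    return calls


def summarize_engraftment(
    calls: list[ColonizationCall],
    table: FeatureTable,
    metadata: SampleMetadata,
) -> EngraftmentSummary:
    """Counts and percentages for one donor x host call set.

    Percentages use the core size as denominator, rounded half away from
    zero to one decimal; mean fecal depth is the arithmetic mean of the
    group's fecal sample totals, rounded to an integer.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    donors = {c.donor_id for c in calls}
    hosts = {c.host for c in calls}
    if len(donors) != 1 or len(hosts) != 1:
        raise ValueError("summarize_engraftment expects calls from one donor x host")
    donor_id, host = donors.pop(), hosts.pop()
    n_core = len(calls)
    n_col = sum(c.status >= Status.colonizer for c in calls)
    n_per = sum(c.status >= Status.persistent_colonizer for c in calls)
    fecal = [
        s for s in metadata.fecal_samples(donor_id=donor_id, host=host)
        if s in set(table.sample_ids)
    ]
    mean_depth = (
        int(round_half_away(float(table.select_samples(fecal).depths().mean())))
        if fecal else 0
    )
    return EngraftmentSummary(
        donor_id=donor_id,
        host=host,
        n_core=n_core,
        n_colonizers=n_col,
        pct_colonizers=percentage(n_col, n_core),
        n_persistent=n_per,
        pct_persistent=percentage(n_per, n_core),
        mean_fecal_depth=mean_depth,
    )


def cross_model_contingency(
    calls_host_a: list[ColonizationCall],
    calls_host_b: list[ColonizationCall],
    basis: Status = Status.colonizer,
) -> CrossModelContingency:
    """Partition one donor's core by reaching ``basis`` in each host."""
    a_by_asv = {c.asv_id: c for c in calls_host_a}
    b_by_asv = {c.asv_id: c for c in calls_host_b}
    if set(a_by_asv) != set(b_by_asv):
        raise ValueError("call lists cover different core sets")
    donors = {c.donor_id for c in calls_host_a} | {c.donor_id for c in calls_host_b}
    if len(donors) != 1:
        raise ValueError("contingency is per donor; got multiple donors")
    host_a = calls_host_a[0].host
    host_b = calls_host_b[0].host
    both = a_only = b_only = neither = 0
    for asv, ca in a_by_asv.items():
        in_a = ca.status >= basis
        in_b = b_by_asv[asv].status >= basis
        if in_a and in_b:
            both += 1
        elif in_a:
            a_only += 1
        elif in_b:
            b_only += 1
        else:
            neither += 1
    return CrossModelContingency(
        donor_id=donors.pop(),
        host_a=host_a,
        host_b=host_b,
        basis=basis,
        both_hosts=both,
        host_a_only=a_only,
        host_b_only=b_only,
        neither=neither,
    )


def rollup_by_taxon(
    calls: list[ColonizationCall],
    taxonomy: TaxonomyTable,
    rank: str,
) -> pd.DataFrame:
    """Group calls by a taxonomic rank.

    Returns a long-format frame with one row per (taxon, host):
    ``taxon, host, n_core, n_colonizers, n_persistent``. ASVs without an
    assignment at the rank are grouped as ``unclassified``. Column sums
    over taxa equal the ungrouped totals.
    """
    if not calls:
        raise ValueError("no calls to roll up")
    labels = taxonomy.rank(rank, asv_ids=[c.asv_id for c in calls])
    rows = []
    for call, taxon in zip(calls, labels):
        rows.append(
            {
                "taxon": taxon,
                "host": call.host,
                "n_core": 1,
                "n_colonizers": int(call.status >= Status.colonizer),
                "n_persistent": int(call.status >= Status.persistent_colonizer),
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["taxon", "host"], as_index=False)[
            ["n_core", "n_colonizers", "n_persistent"]
        ].sum()
    )
    return out.sort_values(["taxon", "host"], ignore_index=True)


def union_rollup(
    calls: list[ColonizationCall],
    taxonomy: TaxonomyTable,
    rank: str,
) -> pd.DataFrame:
    """Roll up over unique ASV identifiers across donors.

    An ASV core in several donors counts once per host; it is a
    union-colonizer of a host when it reached colonizer status in at
    least one donor's calls for that host (persistent likewise).
    """
    if not calls:
        raise ValueError("no calls to roll up")
    best: dict[tuple[str, str], Status] = {}
    for c in calls:
        key = (c.host, c.asv_id)
        if key not in best or c.status > best[key]:
            best[key] = c.status
    rows = []
    for (host, asv), status in best.items():
        rows.append(
            {
                "asv_id": asv,
                "host": host,
                "n_core": 1,
                "n_colonizers": int(status >= Status.colonizer),
                "n_persistent": int(status >= Status.persistent_colonizer),
            }
        )
    df = pd.DataFrame(rows)
    df["taxon"] = taxonomy.rank(rank, asv_ids=df["asv_id"]).to_numpy()
    out = (
        df.groupby(["taxon", "host"], as_index=False)[
            ["n_core", "n_colonizers", "n_persistent"]
        ].sum()
    )
    return out.sort_values(["taxon", "host"], ignore_index=True)


def calls_to_frame(calls: list[ColonizationCall]) -> pd.DataFrame:
    """Flatten calls for TSV export."""
    return pd.DataFrame(
        {
            "donor_id": [c.donor_id for c in calls],
            "host": [c.host for c in calls],
            "asv_id": [c.asv_id for c in calls],
            "status": [str(c.status) for c in calls],
            "n_majority_timepoints": [c.n_majority_timepoints for c in calls],
            "day_detection_fractions": [
                ",".join(f"{f:.6g}" for f in c.day_detection_fractions) for c in calls
            ],
        }
    )
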