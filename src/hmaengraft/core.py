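"""Core donor community identification.

A donor's "core" is the set of ASVs detected in every sequenced aliquot
of that donor's pooled inoculum. Because an aliquot is a resequencing of
the same homogenized material, membership in all aliquots separates the
donor's reliably-sampled taxa from detection noise; the core is the
candidate pool for all downstream engraftment scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import pandas as pd

from .model import FeatureTable, SampleMetadata, StudyDesign

__all__ = ["CoreSet", "identify_core_asvs", "core_read_fraction", "shared_core_asvs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreSet:
    """Ordered set of a donor's core ASVs."""

    donor_id: str
    asv_ids: tuple[str, ...]
    n_aliquots_used: int

    def __len__(self) -> int:
        return len(self.asv_ids)

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in set(self.asv_ids)


def identify_core_asvs(
    table: FeatureTable,
    metadata: SampleMetadata,
    donor_id: str,
    design: StudyDesign | None = None,
) -> CoreSet:
    """ASVs present (count >= detection_min_count) in all of the donor's
    inoculum aliquots.

    Aliquots are taken as they appear in the table; a donor with a
    failed aliquot simply contributes fewer aliquots, recorded in
    ``n_aliquots_used``.
    """
    design = design or StudyDesign()
    aliquots = [s for s in metadata.inoculum_samples(donor_id) if s in set(table.sample_ids)]
    if not aliquots:
        raise ValueError(f"donor {donor_id!r} has no inoculum samples in the table")
    counts = table.select_samples(aliquots).dataframe()
    present_in_all = (counts >= design.detection_min_count).all(axis=0)
    members = tuple(counts.columns[present_in_all])
    return CoreSet(donor_id=donor_id, asv_ids=members, n_aliquots_used=len(aliquots))


def core_read_fraction(
    table: FeatureTable,
    metadata: SampleMetadata,
    donor_id: str,
    core: CoreSet,
) -> tuple[pd.Series, float]:
    """Fraction of inoculum reads captured by the core, per aliquot and
    pooled over aliquots."""
    missing = set(core.asv_ids) - set(table.asv_ids)
    if missing:
        raise ValueError(f"core ASVs absent from the table: {sorted(missing)}")
    aliquots = [s for s in metadata.inoculum_samples(donor_id) if s in set(table.sample_ids)]
    if not aliquots:
        raise ValueError(f"donor {donor_id!r} has no inoculum samples in the table")
    counts = table.select_samples(aliquots).dataframe()
    if not core.asv_ids:
        logger.warning("empty core for donor %s; read fraction is 0", donor_id)
        return pd.Series(0.0, index=aliquots), 0.0
    core_reads = counts[list(core.asv_ids)].sum(axis=1)
    totals = counts.sum(axis=1)
    per_aliquot = core_reads / totals
    pooled = float(core_reads.sum() / totals.sum())
    return per_aliquot, pooled


def shared_core_asvs(cores: list[CoreSet]) -> tuple[str, ...]:
    """ASVs common to every supplied core, ordered by the first core."""
    if len(cores) < 2:
        raise ValueError("need at least two cores to intersect")
    common = reduce(lambda a, b: a & b, (set(c.asv_ids) for c in cores))
    return tuple(a for a in cores[0].asv_ids if a in common)
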