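"""Synthetic engraftment studies with known ground truth.

The generator emulates the statistical shape of a human-to-gnotobiote
transplantation study: per donor, a log-normal rank-abundance community
sequenced as 3-4 multinomial inoculum aliquots, then per recipient
animal a Bernoulli colonization draw per ASV (with phylum-structured
success probabilities, e.g. Firmicutes colonizing mice less readily than
piglets), a multiplicative log-normal distortion of the colonizers'
abundances, an absorbing per-timepoint extinction process, and
multinomial read sampling at realistic depths across the 7-day schedule.

Ground-truth carriage trajectories and colonizer/persistence labels are
emitted alongside the tables so the downstream classifier can be
validated without any sequencing data.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import (
    DEFAULT_SCHEDULE,
    RANKS,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
)

__all__ = [
    "HostSpec",
    "DonorConfig",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedStudy",
    "draw_asv_pool",
    "simulate_donor",
    "sample_aliquots",
    "simulate_engraftment",
    "simulate_study",
    "random_tree",
    "default_study_config",
]

#: Phylum mixture of a typical adult human fecal community.
DEFAULT_PHYLUM_WEIGHTS = {
    "Firmicutes": 0.60,
    "Bacteroidetes": 0.22,
    "Actinobacteriota": 0.08,
    "Proteobacteria": 0.06,
    "Verrucomicrobiota": 0.02,
    "Desulfobacterota": 0.02,
}

#: Host-selective colonization probabilities per phylum. Firmicutes
#: engraft poorly in mice relative to piglets; Bacteroidetes colonize
#: both hosts readily.
MOUSE_COLONIZATION = {
    "Firmicutes": 0.35,
    "Bacteroidetes": 0.85,
    "Actinobacteriota": 0.70,
    "default": 0.50,
}
PIGLET_COLONIZATION = {
    "Firmicutes": 0.70,
    "Bacteroidetes": 0.85,
    "Actinobacteriota": 0.75,
    "default": 0.60,
}


@dataclass(frozen=True)
class HostSpec:
    """Recipient host group of one donor's study arm."""

    host: str
    n_animals: int
    colonization_prob: dict = field(default_factory=dict)
    modulation_sigma: float = 1.0
    extinction_prob: float = 0.02
    fecal_depth: int = 45_000
    #: (animal index, day) pairs with no sample (deaths, missed collections)
    dropouts: tuple = ()

    def prob(self, phylum: str) -> float:
        p = self.colonization_prob.get(
            phylum, self.colonization_prob.get("default", 0.5)
        )
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"colonization probability {p} outside [0, 1]")
        return p


@dataclass(frozen=True)
class DonorConfig:
    donor_id: str
    n_asvs: int
    n_aliquots: int = 4
    aliquot_depth: int = 45_000
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    hosts: tuple = ()

    def __post_init__(self):
        if self.n_asvs < 1:
            raise ValueError("n_asvs must be >= 1")
        if self.n_aliquots < 1 or self.aliquot_depth < 1:
            raise ValueError("aliquot counts and depth must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    donors: tuple
    phylum_weights: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS))
    pool_size: int = 400
    schedule: tuple = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self):
        total = sum(self.phylum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phylum weights must sum to 1")
        if self.pool_size < max(d.n_asvs for d in self.donors):
            raise ValueError("pool_size smaller than the largest donor community")


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator.

    ``colonized`` — per (donor, host): animals x ASVs booleans.
    ``carried``  — per (donor, host, day): animals x ASVs booleans
    (pre-sequencing carriage at sampling time).
    ``labels``   — tidy frame per (donor, host, ASV) with
    ``true_colonizer`` (carried by some animal at some sampled day) and
    ``true_persistent`` (carriage satisfies the >50%-of-animals on >=4
    days rule — the same rule the classifier applies to sequenced
    counts).
    """

    colonized: dict
    carried: dict
    labels: pd.DataFrame


@dataclass
class SimulatedStudy:
    table: FeatureTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    truth: SimulationTruth
    config: SimulationConfig


def draw_asv_pool(pool_size: int, phylum_weights: dict, rng: np.random.Generator) -> TaxonomyTable:
    """Fixed ASV universe shared by all donors of a study.

    Each ASV gets a phylum from the mixture weights and synthetic lower
    ranks nested under it, so taxon roll-ups at phylum/family/genus are
    exercised.
    """
    phyla = list(phylum_weights)
    weights = np.array([phylum_weights[p] for p in phyla], dtype=float)
    assignment = rng.choice(len(phyla), size=pool_size, p=weights)
    rows = []
    for i, k in enumerate(assignment):
        phylum = phyla[k]
        fam = int(rng.integers(1, 4))
        gen = int(rng.integers(1, 3))
        rows.append(
            {
                "asv_id": f"ASV_{i + 1:04d}",
                "domain": "Bacteria",
                "phylum": phylum,
                "class": f"{phylum}_c1",
                "order": f"{phylum}_o1",
                "family": f"{phylum}_f{fam}",
                "genus": f"{phylum}_f{fam}_g{gen}",
                "species": "",
            }
        )
    return TaxonomyTable(pd.DataFrame(rows).set_index("asv_id"))


def simulate_donor(
    cfg: DonorConfig,
    rng: np.random.Generator,
    pool: TaxonomyTable | None = None,
    phylum_weights: dict | None = None,
) -> tuple[pd.Series, TaxonomyTable]:
    """Draw a donor community: normalized exp-normal abundances.

    With a shared ``pool``, the donor's ASVs are sampled from it without
    replacement so identifiers are comparable across donors; otherwise a
    private universe is created from ``phylum_weights``.
    """
    if pool is None:
        pool = draw_asv_pool(cfg.n_asvs, phylum_weights or DEFAULT_PHYLUM_WEIGHTS, rng)
        ids = pool.asv_ids
    else:
        if cfg.n_asvs > len(pool.asv_ids):
            raise ValueError("donor community larger than the ASV pool")
        ids = sorted(rng.choice(pool.asv_ids, size=cfg.n_asvs, replace=False))
    draws = rng.normal(cfg.lognormal_mu, cfg.lognormal_sigma, size=len(ids))
    abund = np.exp(draws)
    abund /= abund.sum()
    taxonomy = TaxonomyTable(pool.data.loc[list(ids)])
    return pd.Series(abund, index=list(ids), name=cfg.donor_id), taxonomy


def sample_aliquots(
    abundances: pd.Series,
    n_aliquots: int,
    depth: int,
    rng: np.random.Generator,
    donor_id: str,
) -> tuple[FeatureTable, SampleMetadata]:
    """Sequence the pooled inoculum: independent multinomial aliquots."""
    if depth < 1 or n_aliquots < 1:
        raise ValueError("depth and n_aliquots must be positive")
    p = abundances.to_numpy(dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    counts = rng.multinomial(depth, p, size=n_aliquots)
    ids = [f"{donor_id}_inoc_{i + 1}" for i in range(n_aliquots)]
    table = FeatureTable(pd.DataFrame(counts, index=ids, columns=list(abundances.index)))
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "donor_id": donor_id,
            "host": "human_donor",
            "sample_type": "inoculum",
            "subject_id": "",
            "day_post_inoculation": "",
        }
    )
    return table, SampleMetadata(meta)


def simulate_engraftment(
    abundances: pd.Series,
    taxonomy: TaxonomyTable,
    host_spec: HostSpec,
    schedule,
    rng: np.random.Generator,
    donor_id: str,
):
    """Longitudinal fecal samples for one donor x host arm, plus truth.

    Per animal: colonization ~ Bernoulli(prob[phylum]); colonized ASVs
    get the donor abundance times LogNormal(0, modulation_sigma),
    renormalized within the animal. Walking the schedule, every carried
    ASV goes extinct with ``extinction_prob`` per time point (absorbing)
    and counts are multinomial(fecal_depth) over the surviving,
    renormalized community. Animals that carry nothing yield zero-count
    samples, left for the depth filter to remove.

    Returns (FeatureTable, SampleMetadata, colonized_frame, carried_by_day).
    """
    asvs = list(abundances.index)
    phyla = taxonomy.rank("phylum", asv_ids=asvs)
    probs = np.array([host_spec.prob(ph) for ph in phyla])
    schedule = list(schedule)
    dropouts = set(host_spec.dropouts)
    animals = [f"{donor_id}_{host_spec.host}_a{i + 1}" for i in range(host_spec.n_animals)]

    colonized = rng.random((host_spec.n_animals, len(asvs))) < probs
    modulation = np.exp(
        rng.normal(0.0, host_spec.modulation_sigma, size=colonized.shape)
    )
    animal_abund = abundances.to_numpy() * modulation * colonized

    carried = colonized.copy()
    carried_by_day: dict[int, pd.DataFrame] = {}
    count_rows, sample_ids, meta_rows = [], [], []
    for day in schedule:
        if host_spec.extinction_prob > 0:
            survive = rng.random(carried.shape) >= host_spec.extinction_prob
            carried = carried & survive
        carried_by_day[day] = pd.DataFrame(
            carried.copy(), index=animals, columns=asvs
        )
        for i, animal in enumerate(animals):
            if (i, day) in dropouts:
                continue
            weights = animal_abund[i] * carried[i]
            total = weights.sum()
            if total > 0:
                counts = rng.multinomial(host_spec.fecal_depth, weights / total)
            else:
                counts = np.zeros(len(asvs), dtype=int)
            sid = f"{animal}_d{day}"
            sample_ids.append(sid)
            count_rows.append(counts)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "donor_id": donor_id,
                    "host": host_spec.host,
                    "sample_type": "fecal",
                    "subject_id": animal,
                    "day_post_inoculation": day,
                }
            )
    table = FeatureTable(pd.DataFrame(count_rows, index=sample_ids, columns=asvs))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    colonized_frame = pd.DataFrame(colonized, index=animals, columns=asvs)
    return table, metadata, colonized_frame, carried_by_day


def _truth_labels(
    donor_id: str,
    host_spec: HostSpec,
    colonized: pd.DataFrame,
    carried_by_day: dict,
    schedule,
    persistence_fraction: float = 0.5,
    persistence_min_timepoints: int = 4,
) -> pd.DataFrame:
    """Colonizer/persistence truth from carriage, mirroring the
    classifier's rule but applied to pre-sequencing carriage flags."""
    animals = list(colonized.index)
    asvs = list(colonized.columns)
    dropouts = set(host_spec.dropouts)
    any_carried = np.zeros(len(asvs), dtype=bool)
    qualifying = np.zeros(len(asvs), dtype=int)
    for day in schedule:
        carried = carried_by_day[day]
        sampled = [a for i, a in enumerate(animals) if (i, day) not in dropouts]
        if not sampled:
            continue
        sub = carried.loc[sampled].to_numpy()
        any_carried |= sub.any(axis=0)
        frac = sub.sum(axis=0) / len(sampled)
        qualifying += frac > persistence_fraction
    return pd.DataFrame(
        {
            "donor_id": donor_id,
            "host": host_spec.host,
            "asv_id": asvs,
            "true_colonizer": any_carried,
            "true_persistent": qualifying >= persistence_min_timepoints,
        }
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Complete seeded study: aliquots plus fecal arms for every donor."""
    rng = np.random.default_rng(config.seed)
    pool = draw_asv_pool(config.pool_size, config.phylum_weights, rng)
    tables, metas, labels = [], [], []
    colonized_truth, carried_truth = {}, {}
    donor_asvs: dict[str, list[str]] = {}
    for donor_cfg in config.donors:
        abund, _tax = simulate_donor(donor_cfg, rng, pool=pool)
        donor_asvs[donor_cfg.donor_id] = list(abund.index)
        inoc_table, inoc_meta = sample_aliquots(
            abund, donor_cfg.n_aliquots, donor_cfg.aliquot_depth, rng,
            donor_cfg.donor_id,
        )
        tables.append(inoc_table)
        metas.append(inoc_meta.data.reset_index())
        for host_spec in donor_cfg.hosts:
            f_table, f_meta, colonized, carried = simulate_engraftment(
                abund, pool, host_spec, config.schedule, rng, donor_cfg.donor_id
            )
            tables.append(f_table)
            metas.append(f_meta.data.reset_index())
            key = (donor_cfg.donor_id, host_spec.host)
            colonized_truth[key] = colonized
            carried_truth[key] = carried
            labels.append(
                _truth_labels(
                    donor_cfg.donor_id, host_spec, colonized, carried,
                    config.schedule,
                )
            )
    table = FeatureTable.concat(tables)
    # union of ASVs across donors, zero-filled; keep pool ordering
    ordered = [a for a in pool.asv_ids if a in set(table.asv_ids)]
    table = table.select_asvs(ordered)
    meta = SampleMetadata(pd.concat(metas, ignore_index=True))
    taxonomy = TaxonomyTable(pool.data.loc[ordered])
    truth = SimulationTruth(
        colonized=colonized_truth,
        carried=carried_truth,
        labels=pd.concat(labels, ignore_index=True),
    )
    return SimulatedStudy(
        table=table, metadata=meta, taxonomy=taxonomy, truth=truth, config=config
    )


def random_tree(asv_ids, rng: np.random.Generator) -> TreeNode:
    """Random rooted binary tree over the given tips.

    Built by repeatedly joining two random subtrees with exponential
    branch lengths — shape-neutral plumbing for UniFrac, not an
    evolutionary model.
    """
    asv_ids = list(asv_ids)
    if not asv_ids:
        raise ValueError("need at least one tip")
    nodes = [f"{a}:{rng.exponential(0.1) + 0.01:.6f}" for a in asv_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.1) + 0.01:.6f}"
        keep = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes = keep + [merged]
    return TreeNode.read(_io.StringIO(nodes[0] + ";"))


def default_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-shaped default: four donors spanning community complexity,
    3-4 inoculum aliquots each, a mouse arm (7-10 animals) and a piglet
    arm (3-4 animals), with one donor's piglet lost after the first
    sampling day and read depths in the mid-tens of thousands."""
    def hosts(n_mice, n_piglets, mouse_depth, piglet_depth, piglet_dropouts=()):
        return (
            HostSpec(
                host="mouse",
                n_animals=n_mice,
                colonization_prob=dict(MOUSE_COLONIZATION),
                fecal_depth=mouse_depth,
            ),
            HostSpec(
                host="piglet",
                n_animals=n_piglets,
                colonization_prob=dict(PIGLET_COLONIZATION),
                fecal_depth=piglet_depth,
                dropouts=piglet_dropouts,
            ),
        )

    # one piglet of the first donor dies after the day-2 collection
    first_donor_dropouts = tuple((3, d) for d in DEFAULT_SCHEDULE[1:])
    donors = (
        DonorConfig(
            donor_id="Donor_1", n_asvs=30, n_aliquots=3,
            hosts=hosts(7, 4, 45_000, 37_000, first_donor_dropouts),
        ),
        DonorConfig(
            donor_id="Donor_2", n_asvs=90, n_aliquots=4,
            hosts=hosts(10, 3, 48_000, 44_000),
        ),
        DonorConfig(
            donor_id="Donor_3", n_asvs=150, n_aliquots=4,
            hosts=hosts(10, 3, 45_000, 40_000),
        ),
        DonorConfig(
            donor_id="Donor_4", n_asvs=140, n_aliquots=4,
            hosts=hosts(10, 3, 46_000, 34_000),
        ),
    )
    params = dict(donors=donors, pool_size=400, seed=seed)
    params.update(overrides)
    return SimulationConfig(**params)
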