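import numpy as np
import pandas as pd
import pytest

from hmaengraft import (
    FeatureTable,
    SampleMetadata,
    StudyDesign,
    default_study_config,
    simulate_study,
)
from hmaengraft.simulate import DonorConfig, HostSpec, SimulationConfig

SCHEDULE = (2, 7, 14, 21, 28, 35, 40)


@pytest.fixture
def design():
    return StudyDesign()


def study_from_presence(presence, donor_id="D1", host="mouse", n_aliquots=3,
                        filler_reads=50, asv_reads=10):
    """Build a minimal study from a boolean (animals x days x ASVs) tensor.

    Each present cell becomes ``asv_reads`` counts in that animal/day
    sample; a filler ASV keeps every sample at positive depth. Aliquots
    contain every ASV so the whole tensor is core.
    """
    presence = np.asarray(presence, dtype=bool)
    n_animals, n_days, n_asvs = presence.shape
    assert n_days == len(SCHEDULE)
    asvs = [f"asv{k}" for k in range(n_asvs)] + ["filler"]
    rows, ids, meta = [], [], []
    for i in range(n_aliquots):
        sid = f"{donor_id}_inoc_{i}"
        ids.append(sid)
        rows.append([asv_reads] * n_asvs + [filler_reads])
        meta.append((sid, donor_id, "human_donor", "inoculum", "", ""))
    for a in range(n_animals):
        subject = f"{donor_id}_{host}_a{a}"
        for d, day in enumerate(SCHEDULE):
            sid = f"{subject}_d{day}"
            ids.append(sid)
            rows.append(
                [asv_reads if presence[a, d, k] else 0 for k in range(n_asvs)]
                + [filler_reads]
            )
            meta.append((sid, donor_id, host, "fecal", subject, day))
    table = FeatureTable(pd.DataFrame(rows, index=ids, columns=asvs))
    metadata = SampleMetadata(
        pd.DataFrame(
            meta,
            columns=["sample_id", "donor_id", "host", "sample_type", "subject_id",
                     "day_post_inoculation"],
        )
    )
    return table, metadata


@pytest.fixture(scope="session")
def sim_study():
    """Study-shaped simulation under the default (realistic) conditions."""
    return simulate_study(default_study_config(seed=7))


def saturated_config(seed=0):
    """Detection-favourable regime: certain colonization, no extinction,
    no abundance modulation, deep sequencing."""
    certain = {"default": 1.0}
    def hosts(n_a, n_b):
        return (
            HostSpec(host="mouse", n_animals=n_a, colonization_prob=dict(certain),
                     modulation_sigma=0.0, extinction_prob=0.0, fecal_depth=500_000),
            HostSpec(host="piglet", n_animals=n_b, colonization_prob=dict(certain),
                     modulation_sigma=0.0, extinction_prob=0.0, fecal_depth=500_000),
        )
    donors = tuple(
        DonorConfig(donor_id=f"Donor_{i+1}", n_asvs=n, n_aliquots=4,
                    aliquot_depth=500_000, hosts=hosts(4, 3))
        for i, n in enumerate((25, 50, 60, 40))
    )
    return SimulationConfig(donors=donors, pool_size=120, seed=seed)


@pytest.fixture(scope="session")
def saturated_study():
    return simulate_study(saturated_config(seed=11))
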