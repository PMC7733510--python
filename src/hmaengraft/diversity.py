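"""Alpha/beta diversity support: Shannon index, Bray-Curtis, unweighted
UniFrac, classical PCoA, donor-distance summaries and rank-sum
comparisons.

Alpha diversity is computed on the full ASV table (rare taxa matter for
it); beta diversity for engraftment questions is typically computed on
the core-restricted table, which is the caller's choice of input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from skbio import TreeNode
from skbio.diversity import beta_diversity

from .model import FeatureTable, SampleMetadata, relative_abundance

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "shannon",
    "bray_curtis",
    "unweighted_unifrac",
    "pairwise_distances",
    "pcoa",
    "distance_to_donor",
    "rank_sum_test",
]

METRICS = ("bray_curtis", "unweighted_unifrac")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal distance matrix keyed by sample id."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample_ids")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0:
            raise ValueError("diagonal must be zero")

    def loc(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x axes
    explained: tuple[float, ...]  # proportion per retained axis
    n_negative_eigenvalues: int


def shannon(counts, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base`` to change it.
    """
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index needs a positive total count")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    denom = x.sum() + y.sum()
    if denom <= 0:
        raise ValueError("both vectors are empty")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def _presence_sets_to_matrix(presence_x, presence_y, tips):
    data = np.zeros((2, len(tips)), dtype=int)
    idx = {t: i for i, t in enumerate(tips)}
    for j, s in enumerate((presence_x, presence_y)):
        for t in s:
            data[j, idx[t]] = 1
    return data


def unweighted_unifrac(presence_x, presence_y, tree: TreeNode) -> float:
    """Unweighted UniFrac between two presence sets on a rooted tree.

    Fraction of the branch length of the tree spanned by either
    community that leads exclusively to tips of one of them.
    """
    presence_x, presence_y = set(presence_x), set(presence_y)
    if not presence_x or not presence_y:
        raise ValueError("both communities must contain at least one taxon")
    tips = [t.name for t in tree.tips()]
    missing = (presence_x | presence_y) - set(tips)
    if missing:
        raise ValueError(f"taxa absent from the tree: {sorted(missing)}")
    data = _presence_sets_to_matrix(presence_x, presence_y, tips)
    # presence and tip coverage are checked above; skip skbio's validation
    # so multifurcating roots (e.g. star trees) are accepted
    dm = beta_diversity(
        "unweighted_unifrac", data, ids=["x", "y"], taxa=tips, tree=tree,
        validate=False,
    )
    return float(dm["x", "y"])


def pairwise_distances(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    drop_missing_tips: bool = False,
) -> DistanceMatrix:
    """All-pairs distances between the table's samples.

    Bray-Curtis runs on relative abundances; UniFrac on presence/absence
    and requires a tree. ASVs missing from the tree raise, unless
    ``drop_missing_tips`` removes them first (with a warning).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    ids = table.sample_ids
    if metric == "bray_curtis":
        rel = relative_abundance(table).to_numpy()
        dm = beta_diversity("braycurtis", rel, ids=ids)
        values = dm.data.copy()
    else:
        if tree is None:
            raise ValueError("unweighted UniFrac requires a tree")
        tips = {t.name for t in tree.tips()}
        missing = [a for a in table.asv_ids if a not in tips]
        if missing:
            if not drop_missing_tips:
                raise ValueError(
                    f"{len(missing)} table ASVs are absent from the tree "
                    f"(e.g. {missing[:3]}); pass drop_missing_tips=True to drop them"
                )
            import warnings

            warnings.warn(
                f"dropping {len(missing)} ASVs absent from the tree", stacklevel=2
            )
            table = table.select_asvs([a for a in table.asv_ids if a in tips])
        presence = (table.dataframe().to_numpy() > 0).astype(int)
        dm = beta_diversity(
            "unweighted_unifrac", presence, ids=ids, taxa=table.asv_ids, tree=tree
        )
        values = dm.data.copy()
    values[np.diag_indices_from(values)] = 0.0
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(sample_ids=tuple(ids), values=values)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinate analysis).

    Double-centers -D^2/2, eigendecomposes, keeps the top positive
    eigenvalues; negative eigenvalues (non-Euclidean input) are dropped
    and counted, not corrected.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n = len(dm.sample_ids)
    if n < 2:
        raise ValueError("PCoA needs at least two samples")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(initial=0.0), 1.0) * 1e-10
    n_negative = int((eigvals < -tol).sum())
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    k = min(n_axes, pos_vals.size)
    coords = pos_vecs[:, :k] * np.sqrt(pos_vals[:k])
    total = pos_vals.sum()
    explained = tuple(float(v / total) for v in pos_vals[:k]) if total > 0 else ()
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=coords,
        explained=explained,
        n_negative_eigenvalues=n_negative,
    )


def distance_to_donor(
    table: FeatureTable,
    metadata: SampleMetadata,
    metric: str,
    tree: TreeNode | None = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Distance from each fecal sample to its donor's inoculum.

    Default is the mean of the sample's distances to each aliquot (one
    observation per fecal sample); ``all_pairs=True`` keeps each
    (sample, aliquot) distance as its own observation instead. Output
    columns: sample_id, donor_id, host, day, distance.
    """
    dm = pairwise_distances(table, metric, tree=tree)
    meta = metadata.data
    sample_set = set(table.sample_ids)
    rows = []
    for donor in sorted(meta["donor_id"].unique()):
        aliquots = [s for s in metadata.inoculum_samples(donor) if s in sample_set]
        fecal = [s for s in metadata.fecal_samples(donor_id=donor) if s in sample_set]
        if fecal and not aliquots:
            raise ValueError(f"donor {donor!r} has no inoculum aliquots in the table")
        for s in fecal:
            dists = [dm.loc(s, a) for a in aliquots]
            obs = dists if all_pairs else [float(np.mean(dists))]
            for d in obs:
                rows.append(
                    {
                        "sample_id": s,
                        "donor_id": donor,
                        "host": meta.loc[s, "host"],
                        "day": int(meta.loc[s, "day_post_inoculation"]),
                        "distance": d,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "donor_id", "host", "day", "distance"])


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration of the null when n_a + n_b <= 10 and there are no
    ties; otherwise the tie-corrected, continuity-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size == 1 and b.size == 1:
        raise ValueError("cannot compare two singletons")
    pooled = np.concatenate([a, b])
    exact_ok = pooled.size <= 10 and np.unique(pooled).size == pooled.size
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
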