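"""Donor-like abundance maintenance for persistent colonizers.

For each persistent colonizer the question is whether its abundance in
the recipient animals stayed comparable to the donor inoculum over the
study. Per scheduled day, the animals' counts are compared against the
donor aliquots with a two-group negative-binomial Wald test on
median-of-ratios-normalized counts (a nonparametric rank-sum mode is
available as a fallback); p values are Benjamini-Hochberg adjusted
across the ASVs tested that day. An ASV "maintained a donor-like
abundance" when it was non-significant on at least 4 of the 7 days —
the same threshold object that defines persistence.

The negative-binomial test is a deliberately small core: joint
median-of-ratios size factors, a pooled method-of-moments dispersion per
ASV, and a Wald statistic on the log ratio of group means. Dispersion
shrinkage, outlier filtering and independent filtering, as found in
full differential-abundance frameworks, are intentionally absent; all
output rows carry their ``test_mode`` label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engraftment import ColonizationCall, Status
from .model import FeatureTable, SampleMetadata, StudyDesign

__all__ = [
    "MaintenanceCall",
    "size_factors_median_of_ratios",
    "differential_test",
    "bh_adjust",
    "classify_donor_like",
    "maintenance_analysis",
]

logger = logging.getLogger(__name__)

TEST_MODES = ("nb_wald", "rank_sum")
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class MaintenanceCall:
    """Whether a persistent colonizer kept a donor-like abundance."""

    donor_id: str
    host: str
    asv_id: str
    n_nonsignificant_days: int
    donor_like: bool


def size_factors_median_of_ratios(
    counts: pd.DataFrame, pseudocount: bool = False
) -> pd.Series:
    """Median-of-ratios normalization factors (samples x ASVs input).

    The reference is the per-ASV geometric mean across samples,
    restricted to ASVs positive in every sample; each sample's factor is
    the median over those ASVs of count/reference. ``pseudocount=True``
    adds 1 to every cell first, for matrices without any all-positive
    ASV.
    """
    if counts.shape[0] < 2:
        raise ValueError("size factors need at least two samples")
    mat = counts.to_numpy(dtype=float)
    if pseudocount:
        mat = mat + 1.0
    all_positive = (mat > 0).all(axis=0)
    if not all_positive.any():
        raise ValueError(
            "no ASV has positive counts in every sample; "
            "re-run with pseudocount=True"
        )
    sub = mat[:, all_positive]
    ref = np.exp(np.log(sub).mean(axis=0))  # per-ASV geometric mean
    factors = np.median(sub / ref, axis=1)
    return pd.Series(factors, index=counts.index, name="size_factor")


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact null distribution when small and tie-free; otherwise normal
    # approximation with tie correction (scipy's asymptotic MWU)
    pooled = np.concatenate([a, b])
    exact_ok = len(pooled) <= 10 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def differential_test(
    animal_counts: pd.DataFrame,
    donor_counts: pd.DataFrame,
    factors: pd.Series,
    mode: str = "nb_wald",
) -> pd.DataFrame:
    """Two-group per-ASV test: animals (group A) vs donor aliquots.

    Both inputs are samples x ASVs over the same ASV columns; ``factors``
    must cover every sample. Returns one row per ASV with columns
    ``log2_fold_change`` (animal vs donor, pseudocount 0.5 on normalized
    means, reporting only), ``pvalue`` and ``test_mode``.

    nb_wald: Wald statistic on the log ratio of normalized group means
    under a negative-binomial two-group model with a pooled
    method-of-moments dispersion (floored at 1e-8); two-sided p from a
    Student reference with n_A + n_D - 2 degrees of freedom, which keeps
    the test close to nominal size at the study's group sizes (3-10).

    rank_sum: Wilcoxon rank-sum on per-sample relative abundances, exact
    for small tie-free groups, tie-corrected normal otherwise.
    """
    if mode not in TEST_MODES:
        raise ValueError(f"mode must be one of {TEST_MODES}")
    if list(animal_counts.columns) != list(donor_counts.columns):
        raise ValueError("animal and donor tables must share the same ASV columns")
    n_a, n_d = animal_counts.shape[0], donor_counts.shape[0]
    if n_a < 2 or n_d < 2:
        raise ValueError("both groups need at least two samples")
    missing = (set(animal_counts.index) | set(donor_counts.index)) - set(factors.index)
    if missing:
        raise ValueError(f"size factors missing for samples: {sorted(missing)}")

    asvs = list(animal_counts.columns)
    ka = animal_counts.to_numpy(dtype=float)
    kd = donor_counts.to_numpy(dtype=float)
    sa = factors.loc[animal_counts.index].to_numpy(dtype=float)[:, None]
    sd = factors.loc[donor_counts.index].to_numpy(dtype=float)[:, None]
    qa, qd = ka / sa, kd / sd
    mu_a, mu_d = qa.mean(axis=0), qd.mean(axis=0)
    log2fc = np.log2((mu_a + 0.5) / (mu_d + 0.5))
    all_zero = (ka.sum(axis=0) == 0) & (kd.sum(axis=0) == 0)

    if mode == "rank_sum":
        ra = ka / ka.sum(axis=1, keepdims=True)
        rd = kd / kd.sum(axis=1, keepdims=True)
        pvals = np.ones(len(asvs))
        for j in range(len(asvs)):
            if all_zero[j]:
                continue
            pvals[j] = _rank_sum_p(ra[:, j], rd[:, j])
    else:
        var_a = qa.var(axis=0, ddof=1)
        var_d = qd.var(axis=0, ddof=1)
        var_pool = ((n_a - 1) * var_a + (n_d - 1) * var_d) / (n_a + n_d - 2)
        mu_pool = (n_a * mu_a + n_d * mu_d) / (n_a + n_d)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = (var_pool - mu_pool) / np.square(mu_pool)
        disp = np.where(np.isfinite(disp), disp, 0.0)
        disp = np.maximum(disp, DISPERSION_FLOOR)
        # zero group means have no finite log; floor at half a normalized
        # count spread over the group (numerical guard, not a pseudocount)
        mu_a_t = np.maximum(mu_a, 0.5 / n_a)
        mu_d_t = np.maximum(mu_d, 0.5 / n_d)
        beta = np.log(mu_a_t) - np.log(mu_d_t)
        se = np.sqrt((1.0 / mu_a_t + disp) / n_a + (1.0 / mu_d_t + disp) / n_d)
        wald = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(wald), df=n_a + n_d - 2)
        pvals = np.minimum(pvals, 1.0)
        pvals[all_zero] = 1.0

    log2fc = np.where(all_zero, 0.0, log2fc)
    return pd.DataFrame(
        {
            "asv_id": asvs,
            "log2_fold_change": log2fc,
            "pvalue": pvals,
            "test_mode": mode,
        }
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def classify_donor_like(
    results: pd.DataFrame,
    persistent_calls: list[ColonizationCall],
    design: StudyDesign | None = None,
) -> list[MaintenanceCall]:
    """Aggregate per-day adjusted p values into maintenance calls.

    ``results`` holds one row per (asv_id, day) with a ``padj`` column.
    A day counts as non-significant when padj >= alpha; days without a
    test (no samples) count as neither, leaving the >= 4-of-7 rule
    conservative under missingness. Only ASVs already called persistent
    are eligible; rows for other ASVs are skipped with a log entry.
    """
    design = design or StudyDesign()
    persistent = {
        c.asv_id: c for c in persistent_calls
        if c.status >= Status.persistent_colonizer
    }
    skipped = set(results["asv_id"]) - set(persistent)
    if skipped:
        logger.info(
            "skipping %d non-persistent ASVs in maintenance scoring", len(skipped)
        )
    calls = []
    grouped = results[results["asv_id"].isin(persistent)].groupby("asv_id")
    counts = {
        asv: int((g["padj"] >= design.alpha).sum()) for asv, g in grouped
    }
    for asv, call in persistent.items():
        n_ns = counts.get(asv, 0)
        calls.append(
            MaintenanceCall(
                donor_id=call.donor_id,
                host=call.host,
                asv_id=asv,
                n_nonsignificant_days=n_ns,
                donor_like=n_ns >= design.persistence_min_timepoints,
            )
        )
    return calls


def maintenance_analysis(
    table: FeatureTable,
    metadata: SampleMetadata,
    persistent_calls: list[ColonizationCall],
    design: StudyDesign | None = None,
    mode: str = "nb_wald",
    bh_scope: str = "per_day",
) -> tuple[pd.DataFrame, list[MaintenanceCall]]:
    """Per-day donor-vs-animal tests for one donor x host, plus calls.

    Size factors are fitted jointly on the day's animal samples and the
    donor aliquots over all ASVs (pseudocount fallback when no ASV is
    positive everywhere); tests are restricted to the persistent
    colonizers. ``bh_scope`` is ``per_day`` (adjust across ASVs within
    each day, the default) or ``global`` (one family across all days).
    """
    design = design or StudyDesign()
    if bh_scope not in ("per_day", "global"):
        raise ValueError("bh_scope must be 'per_day' or 'global'")
    persistent = [c for c in persistent_calls if c.status >= Status.persistent_colonizer]
    if not persistent:
        return pd.DataFrame(
            columns=["asv_id", "day", "log2_fold_change", "pvalue", "padj", "test_mode"]
        ), []
    donor_id = persistent[0].donor_id
    host = persistent[0].host
    asvs = [c.asv_id for c in persistent]
    sample_set = set(table.sample_ids)
    aliquots = [s for s in metadata.inoculum_samples(donor_id) if s in sample_set]
    if len(aliquots) < 2:
        raise ValueError(f"donor {donor_id!r} needs >= 2 inoculum aliquots for testing")

    day_results = []
    for day in design.schedule:
        animals = [
            s for s in metadata.fecal_samples(donor_id=donor_id, host=host, day=day)
            if s in sample_set
        ]
        if len(animals) < 2:
            logger.warning(
                "day %s for donor %s / %s has %d samples; not tested",
                day, donor_id, host, len(animals),
            )
            continue
        sub = table.select_samples(animals + aliquots).dataframe()
        try:
            factors = size_factors_median_of_ratios(sub)
        except ValueError:
            factors = size_factors_median_of_ratios(sub, pseudocount=True)
        res = differential_test(
            sub.loc[animals, asvs], sub.loc[aliquots, asvs], factors, mode=mode
        )
        res.insert(1, "day", day)
        if bh_scope == "per_day":
            res["padj"] = bh_adjust(res["pvalue"].to_numpy())
        day_results.append(res)

    if not day_results:
        results = pd.DataFrame(
            columns=["asv_id", "day", "log2_fold_change", "pvalue", "padj", "test_mode"]
        )
    else:
        results = pd.concat(day_results, ignore_index=True)
        if bh_scope == "global":
            results["padj"] = bh_adjust(results["pvalue"].to_numpy())
    calls = classify_donor_like(results, persistent, design)
    return results, calls
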