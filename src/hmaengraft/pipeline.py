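"""End-to-end orchestration and report writing.

Runs the analysis in its natural order — depth filter, core
identification, colonization/persistence classification, cross-host
contingency, taxon roll-ups, shared-core report, donor-like maintenance,
diversity — and writes every intermediate as a commented TSV so any
stage can be audited or replaced. Deterministic given inputs; the run
manifest echoes the configuration, package versions and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import maintenance_analysis
from .core import core_read_fraction, identify_core_asvs, shared_core_asvs
from .diversity import distance_to_donor, pairwise_distances, pcoa, shannon
from .engraftment import (
    Status,
    calls_to_frame,
    classify_persistent,
    cross_model_contingency,
    detect_presence,
    rollup_by_taxon,
    summarize_engraftment,
    union_rollup,
)
from .model import (
    FeatureTable,
    SampleMetadata,
    StudyDesign,
    TaxonomyTable,
    filter_samples_by_depth,
    relative_abundance,
    validate_study,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report_tsv"]

logger = logging.getLogger(__name__)

ROLLUP_RANKS = ("phylum", "family", "genus")


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    out_dir: Path
    design: StudyDesign = field(default_factory=StudyDesign)
    test_mode: str = "nb_wald"
    bh_scope: str = "per_day"
    beta_metric: str = "bray_curtis"
    core_restricted_beta: bool = True
    force: bool = False

    def hash(self) -> str:
        payload = json.dumps(
            {
                "design": dataclasses.asdict(self.design),
                "test_mode": self.test_mode,
                "bh_scope": self.bh_scope,
                "beta_metric": self.beta_metric,
                "core_restricted_beta": self.core_restricted_beta,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report_tsv(df: pd.DataFrame, path: Path, stage: str, config_hash: str,
                     index: bool = False) -> None:
    """TSV with a provenance comment line (stage + config hash)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# hmaengraft stage={stage} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _checksum(table: FeatureTable) -> str:
    return hashlib.sha256(
        table.dataframe().to_csv(sep="\t").encode()
    ).hexdigest()[:16]


def run_pipeline(
    table: FeatureTable,
    metadata: SampleMetadata,
    config: PipelineConfig,
    taxonomy: TaxonomyTable | None = None,
    tree=None,
) -> dict:
    """Run every stage and write the output bundle under ``out_dir``.

    Returns a dict of in-memory results keyed by stage name. Raises
    :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    chash = config.hash()
    results: dict = {}

    # -- filter + validate ------------------------------------------------
    raw_checksum = _checksum(table)
    n_samples_in, n_asvs_in = table.shape
    table = filter_samples_by_depth(table, design.min_sample_depth)
    logger.info(
        "depth filter (< %d reads): %d -> %d samples, %d ASVs",
        design.min_sample_depth, n_samples_in, table.shape[0], n_asvs_in,
    )
    report = validate_study(table, metadata, design)
    results["validation"] = report
    if not report.ok and not config.force:
        raise PipelineError(
            "validate",
            f"study validation failed ({report}); pass force=True to continue",
        )
    metadata = metadata.subset([s for s in metadata.sample_ids if s in set(table.sample_ids)])
    donors = metadata.donors()
    hosts = metadata.hosts()

    # -- core identification ----------------------------------------------
    try:
        cores = {d: identify_core_asvs(table, metadata, d, design) for d in donors}
    except ValueError as exc:
        raise PipelineError("core", str(exc)) from exc
    core_rows, frac_rows = [], []
    for d, core in cores.items():
        per_aliquot, pooled = core_read_fraction(table, metadata, d, core)
        core_rows += [{"donor_id": d, "asv_id": a} for a in core.asv_ids]
        frac_rows.append(
            {
                "donor_id": d,
                "n_core": len(core),
                "n_aliquots_used": core.n_aliquots_used,
                "pooled_core_read_fraction": pooled,
                **{f"aliquot_{s}": f for s, f in per_aliquot.items()},
            }
        )
    write_report_tsv(pd.DataFrame(core_rows), out / "core_sets.tsv", "core", chash)
    write_report_tsv(pd.DataFrame(frac_rows), out / "core_read_fractions.tsv", "core", chash)
    results["cores"] = cores

    if len(donors) >= 2:
        shared = shared_core_asvs([cores[d] for d in donors])
        write_report_tsv(
            pd.DataFrame({"asv_id": list(shared)}), out / "shared_core_asvs.tsv",
            "core", chash,
        )
        results["shared_core"] = shared

    # -- classification ----------------------------------------------------
    presence = detect_presence(table, design)
    calls, summaries = {}, []
    for d in donors:
        for h in hosts:
            if not metadata.fecal_samples(donor_id=d, host=h):
                continue
            try:
                group_calls = classify_persistent(
                    presence, metadata, d, h, cores[d], design
                )
            except ValueError as exc:
                raise PipelineError("classify", str(exc)) from exc
            calls[(d, h)] = group_calls
            summaries.append(summarize_engraftment(group_calls, table, metadata))
    all_calls = [c for group in calls.values() for c in group]
    write_report_tsv(calls_to_frame(all_calls), out / "colonization_calls.tsv", "classify", chash)
    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    write_report_tsv(summary_df, out / "engraftment_summary.tsv", "classify", chash)
    results["calls"] = calls
    results["summaries"] = summaries

    # -- contingency ---------------------------------------------------------
    contingencies = []
    if len(hosts) == 2:
        a, b = hosts
        for d in donors:
            if (d, a) in calls and (d, b) in calls:
                contingencies.append(
                    cross_model_contingency(calls[(d, a)], calls[(d, b)], Status.colonizer)
                )
        cont_df = pd.DataFrame(
            [
                {
                    "donor_id": c.donor_id, "host_a": c.host_a, "host_b": c.host_b,
                    "basis": str(c.basis), "both_hosts": c.both_hosts,
                    "host_a_only": c.host_a_only, "host_b_only": c.host_b_only,
                    "neither": c.neither,
                }
                for c in contingencies
            ]
        )
        write_report_tsv(cont_df, out / "cross_model_contingency.tsv", "classify", chash)
    results["contingency"] = contingencies

    # -- taxon roll-ups ------------------------------------------------------
    if taxonomy is not None and all_calls:
        for rank in ROLLUP_RANKS:
            per_donor = []
            for d in donors:
                donor_calls = [c for group_key, group in calls.items()
                               if group_key[0] == d for c in group]
                if not donor_calls:
                    continue
                r = rollup_by_taxon(donor_calls, taxonomy, rank)
                r.insert(0, "donor_id", d)
                per_donor.append(r)
            write_report_tsv(
                pd.concat(per_donor, ignore_index=True),
                out / f"rollup_{rank}.tsv", "classify", chash,
            )
        union = union_rollup(all_calls, taxonomy, "phylum")
        write_report_tsv(union, out / "rollup_union_phylum.tsv", "classify", chash)
        results["union_rollup"] = union

    # -- chord / heatmap exports ----------------------------------------------
    rel = relative_abundance(table)
    chord_rows = []
    for (d, h), group in calls.items():
        fecal = metadata.fecal_samples(donor_id=d, host=h)
        sub = rel.loc[fecal]
        for c in group:
            if c.status >= Status.colonizer:
                chord_rows.append(
                    {
                        "donor_id": d, "host": h, "asv_id": c.asv_id,
                        "mean_relative_abundance": float(sub[c.asv_id].mean()),
                        "link_weight": int(c.status),
                    }
                )
    write_report_tsv(pd.DataFrame(chord_rows), out / "chord_edges.tsv", "classify", chash)

    # -- maintenance ------------------------------------------------------------
    maint_frames, maint_calls = [], []
    for (d, h), group in calls.items():
        try:
            res, mcalls = maintenance_analysis(
                table, metadata, group, design,
                mode=config.test_mode, bh_scope=config.bh_scope,
            )
        except ValueError as exc:
            raise PipelineError("maintain", str(exc)) from exc
        if not res.empty:
            res.insert(0, "donor_id", d)
            res.insert(1, "host", h)
            maint_frames.append(res)
        maint_calls += mcalls
    if maint_frames:
        write_report_tsv(
            pd.concat(maint_frames, ignore_index=True),
            out / "differential_tests.tsv", "maintain", chash,
        )
    write_report_tsv(
        pd.DataFrame([dataclasses.asdict(m) for m in maint_calls]),
        out / "maintenance_calls.tsv", "maintain", chash,
    )
    results["maintenance"] = maint_calls

    # -- diversity ----------------------------------------------------------------
    alpha = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "shannon": [shannon(row) for row in table.dataframe().to_numpy()],
        }
    )
    write_report_tsv(alpha, out / "alpha_diversity.tsv", "diversity", chash)
    beta_table = table
    if config.core_restricted_beta:
        core_union = sorted({a for core in cores.values() for a in core.asv_ids})
        keep = [s for s, t in zip(table.sample_ids, table.select_asvs(core_union).depths())
                if t > 0]
        beta_table = table.select_asvs(core_union).select_samples(keep)
    try:
        dm = pairwise_distances(
            beta_table, config.beta_metric,
            tree=tree, drop_missing_tips=tree is not None,
        )
    except ValueError as exc:
        raise PipelineError("diversity", str(exc)) from exc
    write_report_tsv(dm.dataframe(), out / f"distance_{config.beta_metric}.tsv",
                     "diversity", chash, index=True)
    ord_res = pcoa(dm, n_axes=2)
    ord_df = pd.DataFrame(
        ord_res.coordinates,
        index=list(ord_res.sample_ids),
        columns=[f"axis{i + 1}" for i in range(ord_res.coordinates.shape[1])],
    )
    ord_df.index.name = "sample_id"
    write_report_tsv(ord_df, out / "pcoa.tsv", "diversity", chash, index=True)
    donor_dist = distance_to_donor(
        beta_table, metadata.subset(beta_table.sample_ids), config.beta_metric,
        tree=tree,
    )
    write_report_tsv(donor_dist, out / "distance_to_donor.tsv", "diversity", chash)
    results["alpha"] = alpha
    results["ordination"] = ord_res
    results["distance_to_donor"] = donor_dist

    # -- manifest --------------------------------------------------------------------
    manifest = {
        "package": "hmaengraft",
        "version": __version__,
        "config_hash": chash,
        "design": dataclasses.asdict(design),
        "test_mode": config.test_mode,
        "bh_scope": config.bh_scope,
        "beta_metric": config.beta_metric,
        "input_checksum": raw_checksum,
        "n_samples_analyzed": table.shape[0],
        "n_asvs": table.shape[1],
        "donors": donors,
        "hosts": hosts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
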