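"""End-to-end pipeline: simulate -> featurize -> cleanse -> weight ->
select -> sweep -> motif -> site mapping -> similarity.

``run_pipeline`` writes only deterministic data files (stage timings go to
the logger, not to disk), so two runs with the same seed are byte-for-byte
identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import motif as motif_mod
from . import simulate as simulate_mod
from . import trees as trees_mod
from . import weighting as weighting_mod
from .cleanse import cleanse as _cleanse
from .featurize import featurize_all as _featurize_all
from .config import PipelineConfig, fork_seed
from .io import (
    AttributeTable,
    write_attribute_table,
    write_fasta,
    write_labels,
)

log = logging.getLogger("nkaminer")


@dataclass
class PipelineResult:
    records: list
    reference: object
    truth: list
    attributes: AttributeTable
    fcd_organism: AttributeTable
    fcd_isoform: AttributeTable
    weights: dict          # task -> {algorithm -> WeightVector}
    datasets: dict         # task -> {name -> AttributeTable}
    sweeps: dict           # task -> SweepResult
    motif_prevalence: dict
    site_report: object
    similarity: pd.DataFrame


def _weights_frame(weights: dict) -> pd.DataFrame:
    return pd.DataFrame({alg: wv.weights for alg, wv in sorted(weights.items())})


def run_pipeline(
    config: PipelineConfig,
    sim_config: simulate_mod.SimConfig | None = None,
    out_dir=None,
    similarity_per_group: int = 4,
) -> PipelineResult:
    """Run every stage on a simulated dataset; optionally write outputs."""
    t0 = time.perf_counter()
    sim_config = sim_config or simulate_mod.SimConfig(
        seed=fork_seed(config.random_seed, "simulate")
    )
    records, reference, truth = simulate_mod.simulate_dataset(sim_config)
    log.info("simulate: %d records (%.1fs)", len(records), time.perf_counter() - t0)

    t = time.perf_counter()
    table = _featurize_all(records)
    log.info("featurize: %s attributes (%.1fs)", table.data.shape[1],
             time.perf_counter() - t)

    # organism-group task uses all rows; isoform task the vertebrates only
    t = time.perf_counter()
    fcd_org = _cleanse(
        table, config.sd_threshold, config.correlation_threshold
    ).table
    vert = table.rows(table.labels["group"] == "vertebrate")
    fcd_iso = _cleanse(
        vert, config.sd_threshold, config.correlation_threshold
    ).table
    log.info("cleanse: organism %d, isoform %d attributes kept (%.1fs)",
             fcd_org.data.shape[1], fcd_iso.data.shape[1], time.perf_counter() - t)

    weights: dict[str, dict] = {}
    datasets: dict[str, dict] = {}
    sweeps: dict[str, trees_mod.SweepResult] = {}
    for task, fcd, label_col in (
        ("organism_groups", fcd_org, "group"),
        ("isoforms", fcd_iso, "isoform"),
    ):
        t = time.perf_counter()
        weights[task] = weighting_mod.weight_all(fcd, label_col)
        datasets[task] = weighting_mod.make_all_datasets(
            fcd, label_col, task, weights[task]
        )
        log.info("weighting[%s]: 10 algorithms (%.1fs)", task,
                 time.perf_counter() - t)
        t = time.perf_counter()
        sweeps[task] = trees_mod.run_sweep(
            datasets[task], label_col,
            folds=config.cv_folds,
            seed=fork_seed(config.random_seed, f"sweep:{task}"),
            params=config.tree_params,
        )
        log.info("sweep[%s]: best %.2f%% at %s (%.1fs)", task,
                 sweeps[task].best_value, sweeps[task].best_cells[0],
                 time.perf_counter() - t)

    t = time.perf_counter()
    prevalence = motif_mod.motif_prevalence(records)
    site_report = motif_mod.site_state_table(records, reference, config.sites)
    log.info("motif+sites (%.1fs)", time.perf_counter() - t)

    t = time.perf_counter()
    subsample = [
        r
        for g in sorted({r.group for r in records})
        for r in [x for x in records if x.group == g][:similarity_per_group]
    ]
    similarity = motif_mod.group_similarity(subsample)
    log.info("similarity on %d sequences (%.1fs)", len(subsample),
             time.perf_counter() - t)

    result = PipelineResult(
        records=records, reference=reference, truth=truth, attributes=table,
        fcd_organism=fcd_org, fcd_isoform=fcd_iso, weights=weights,
        datasets=datasets, sweeps=sweeps, motif_prevalence=prevalence,
        site_report=site_report, similarity=similarity,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    log.info("pipeline done (%.1fs total)", time.perf_counter() - t0)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.records, out / "simulated.fasta")
    write_fasta([result.reference], out / "reference.fasta")
    write_labels(result.records, out / "labels.tsv")
    simulate_mod.truth_to_json(result.truth, out / "truth.json")
    write_attribute_table(result.attributes, out / "attributes.tsv")
    write_attribute_table(result.fcd_organism, out / "fcd_organism.tsv")
    write_attribute_table(result.fcd_isoform, out / "fcd_isoform.tsv")
    for task in result.weights:
        tag = "organism" if task == "organism_groups" else "isoform"
        _weights_frame(result.weights[task]).to_csv(
            out / f"weights_{tag}.tsv", sep="\t", float_format="%.12g"
        )
        rows = [
            {"dataset": name, "n_attributes": t.data.shape[1],
             "attributes": ",".join(t.attributes)}
            for name, t in result.datasets[task].items()
        ]
        pd.DataFrame(rows).to_csv(out / f"datasets_{tag}.tsv", sep="\t", index=False)
        result.sweeps[task].to_tsv(out / f"sweep_{tag}.tsv")
        (out / f"best_tree_{tag}.txt").write_text(
            f"cell: {result.sweeps[task].best_tree_cell}\n"
            + result.sweeps[task].best_tree.to_text()
            + "\n\nroutes:\n"
            + "\n".join(str(r) for r in result.sweeps[task].routes)
            + "\n"
        )
    pd.Series(result.motif_prevalence, name="percent_with_motif").to_csv(
        out / "motif_prevalence.tsv", sep="\t"
    )
    result.site_report.per_sequence.to_csv(
        out / "sites_per_sequence.tsv", sep="\t", index_label="id"
    )
    long_rows = []
    for pos, frame in sorted(result.site_report.group_percent.items()):
        for grp in frame.index:
            for state in frame.columns:
                long_rows.append(
                    {"site": pos, "label": grp, "state": state,
                     "percent": frame.loc[grp, state]}
                )
    for pos, frame in sorted(result.site_report.isoform_percent.items()):
        for iso in frame.index:
            for state in frame.columns:
                long_rows.append(
                    {"site": pos, "label": iso, "state": state,
                     "percent": frame.loc[iso, state]}
                )
    pd.DataFrame(long_rows).to_csv(
        out / "site_percent.tsv", sep="\t", index=False, float_format="%.12g"
    )
    result.similarity.to_csv(out / "similarity.tsv", sep="\t", float_format="%.12g")
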