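"""End-to-end orchestration: simulate/load -> DE -> concordance -> enrichment.

A run is driven by a :class:`RunConfig`, executes the stages in dependency
order, writes one CSV per stage output plus a machine-readable ``report.json``
and a human-readable ``report.txt``, and is deterministic given its seed (all
stage randomness flows from the single top-level seed via named substreams).

Enrichment runs separately on the *consistent* and *opposite* ortholog
classes, against the universe of orthologs present in all species after
mapping (the background actually tested), unless a universe is supplied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from xsci import concordance, conservation, diffexpr, enrichment, interactome
from xsci.io import ExpressionStudy, GeneSetCollection
from xsci.simulate import (
    CONSERVATION_TREE,
    SimulatedDataset,
    SimulationConfig,
    simulate_alignment,
    simulate_dataset,
    simulate_edges,
)

logger = logging.getLogger(__name__)

#: the salamander annotation reaches the mouse reference through human
DEFAULT_CHAIN: dict[str, tuple[str, ...]] = {"salamander": ("human",)}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outgroup: str = "salamander"
    alpha: float = 0.05
    k_gene_clusters: int = 4
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_gene_clusters < 1:
            raise ValueError("k_gene_clusters must be >= 1")
        species = {sp for _, sp, _, _ in self.simulation.species_plan}
        if self.outgroup not in species:
            raise ValueError(
                f"outgroup {self.outgroup!r} has no study in the species plan"
            )


@dataclass
class RunResult:
    """Everything a pipeline run produced, in memory."""

    config: RunConfig
    dataset: SimulatedDataset
    de_tables: dict[str, pd.DataFrame]
    records: pd.DataFrame
    counts: concordance.PartitionCounts
    enrichment_tables: dict[str, pd.DataFrame]
    report: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute simulate -> DE -> concordance -> enrichment and report.

    Raises with the stage name on any stage failure.  When ``config.outdir``
    is set, every stage output is written there as CSV along with the report.
    """
    report: dict = {"config": _serialize_config(config), "stages": {}}

    # stage 1: data ------------------------------------------------------
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    try:
        dataset = simulate_dataset(sim_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    report["stages"]["simulate"] = {
        "n_genes": sim_cfg.n_genes,
        "n_studies": len(dataset.studies),
        "planted": {
            "consistent": len(dataset.truth.consistent_genes),
            "opposite": len(dataset.truth.opposite_genes),
            "null": len(dataset.truth.null_genes),
        },
    }

    # stage 2: per-study DE + collapsing --------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    species_of: dict[str, str] = {}
    for study in dataset.studies:
        try:
            per_probeset, prior = diffexpr.fit_moderated_t(study)
            per_gene = diffexpr.collapse_probesets(per_probeset)
        except Exception as exc:
            raise RuntimeError(
                f"stage de failed for study {study.study_id!r}: {exc}"
            ) from exc
        de_tables[study.study_id] = per_gene
        species_of[study.study_id] = study.species
        report["stages"].setdefault("de", {})[study.study_id] = {
            "n_probesets": int(len(study.matrix)),
            "n_genes": int(len(per_gene)),
            "prior_d0": round(prior.d0, 4) if np.isfinite(prior.d0) else "inf",
            "prior_s0_sq": round(prior.s0_sq, 6),
            "n_significant": int((per_gene["p_adj"] <= config.alpha).sum()),
        }

    # stage 3: ortholog mapping + concordance ----------------------------
    try:
        ortho = concordance.OrthologMap.from_table(dataset.ortholog_table)
        mapped = concordance.map_to_reference(
            {sid: (species_of[sid], df) for sid, df in de_tables.items()},
            ortho,
            chain=DEFAULT_CHAIN,
        )
        records, counts = concordance.intersect_and_classify(
            mapped, outgroup=config.outgroup, alpha=config.alpha
        )
    except Exception as exc:
        raise RuntimeError(f"stage concordance failed: {exc}") from exc
    report["stages"]["concordance"] = {
        "n_in_all_species": int(len(records)),
        "n_significant": counts.n_significant,
        "n_consistent": counts.n_consistent,
        "n_opposite": counts.n_opposite,
        "n_other": counts.n_other,
    }

    # stage 4: enrichment per class --------------------------------------
    universe = sorted(records.index)
    enrichment_tables: dict[str, pd.DataFrame] = {}
    sig = records[records["significant_all"].astype(bool)]
    for label, pattern in (("consistent", "consistent"),
                           ("opposite", "opposite_outgroup")):
        query = sorted(sig.index[sig["pattern"] == pattern])
        try:
            table = enrichment.hypergeom_enrich(
                query, dataset.gene_sets, universe, p_adj_max=None
            )
        except Exception as exc:
            raise RuntimeError(f"stage enrichment ({label}) failed: {exc}") from exc
        enrichment_tables[label] = table
        significant = table[table["p_adj"] <= config.alpha]
        report["stages"].setdefault("enrichment", {})[label] = {
            "n_query": len(query),
            "n_sets_tested": int(len(table)),
            "n_significant_sets": int(len(significant)),
            "top_term": significant.iloc[0]["term_id"] if len(significant) else None,
        }

    # stage 5: heatmap ordering of the significant orthologs ---------------
    fc_cols = [c for c in records.columns if c.startswith("log2fc_")]
    fc_matrix = sig[fc_cols].rename(
        columns=lambda c: c.removeprefix("log2fc_")
    )
    if len(fc_matrix) >= config.k_gene_clusters and len(fc_cols) >= 2:
        try:
            study_order, gene_clusters = conservation.order_for_heatmap(
                fc_matrix, n_gene_clusters=config.k_gene_clusters,
                seed=config.seed,
            )
        except Exception as exc:
            raise RuntimeError(f"stage heatmap failed: {exc}") from exc
        cluster_sizes = gene_clusters.value_counts().sort_index()
        report["stages"]["heatmap"] = {
            "study_order": study_order,
            "gene_cluster_sizes": {int(k): int(v)
                                   for k, v in cluster_sizes.items()},
        }
    else:
        report["stages"]["heatmap"] = {"skipped": "too few significant genes"}

    # stage 6: conservation demonstration ---------------------------------
    try:
        aln = simulate_alignment(
            CONSERVATION_TREE, n_sites=2000, seed=(config.seed + 211) % 2**31
        )
        pid = conservation.percent_identity(aln, "human")
        tree = conservation.neighbor_joining(conservation.poisson_distance(aln))
    except Exception as exc:
        raise RuntimeError(f"stage conservation failed: {exc}") from exc
    report["stages"]["conservation"] = {
        "n_taxa": len(aln.taxa),
        "min_pct_identity_vs_human": float(pid.min()),
        "max_pct_identity_vs_human": float(pid.drop("human").max()),
        "nj_newick": _newick_string(tree),
    }

    # stage 7: interaction network ----------------------------------------
    class_genes = sorted(sig.index[sig["pattern"].isin(
        ["consistent", "opposite_outgroup"])])
    try:
        edges = simulate_edges(
            hub_genes=sorted(sig.index[sig["pattern"] == "consistent"]),
            other_genes=universe,
            seed=(config.seed + 409) % 2**31,
        )
        filtered, node_order = interactome.filter_network(
            edges, cutoff=0.4, query_nodes=class_genes
        )
    except Exception as exc:
        raise RuntimeError(f"stage network failed: {exc}") from exc
    report["stages"]["network"] = {
        "n_edges_kept": int(len(filtered)),
        "n_nodes": len(node_order),
        "top_degree_nodes": node_order[:5],
    }

    result = RunResult(
        config=config,
        dataset=dataset,
        de_tables=de_tables,
        records=records,
        counts=counts,
        enrichment_tables=enrichment_tables,
        report=report,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def _newick_string(tree) -> str:
    import io as _stdio

    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _serialize_config(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["simulation"]["species_plan"] = [
        list(entry) for entry in config.simulation.species_plan
    ]
    return d


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, df in result.de_tables.items():
        df.to_csv(outdir / f"de_{sid}.csv", lineterminator="\n")
    result.records.to_csv(outdir / "concordance.csv", lineterminator="\n")
    for label, df in result.enrichment_tables.items():
        df.to_csv(outdir / f"enrichment_{label}.csv", index=False,
                  lineterminator="\n")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(format_report(result.report))
    logger.info("pipeline outputs written to %s", outdir)


def format_report(report: Mapping) -> str:
    """Render the JSON run report as a short human-readable summary."""
    lines = ["pipeline run report", "==================="]
    conc = report["stages"].get("concordance", {})
    lines.append(
        f"orthologs in all species: {conc.get('n_in_all_species', 0)}"
    )
    lines.append(
        "significant in all studies: "
        f"{conc.get('n_significant', 0)} "
        f"(consistent {conc.get('n_consistent', 0)}, "
        f"opposite-in-outgroup {conc.get('n_opposite', 0)}, "
        f"other {conc.get('n_other', 0)})"
    )
    for label, info in report["stages"].get("enrichment", {}).items():
        lines.append(
            f"enrichment [{label}]: {info['n_significant_sets']} significant "
            f"set(s) of {info['n_sets_tested']} tested "
            f"(top: {info['top_term']})"
        )
    for sid, info in report["stages"].get("de", {}).items():
        lines.append(
            f"de [{sid}]: {info['n_significant']} / {info['n_genes']} genes "
            f"at p_adj <= alpha (prior d0 = {info['prior_d0']})"
        )
    return "\n".join(lines) + "\n"
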