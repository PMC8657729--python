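"""Synthetic multi-species SCI datasets with known planted structure.

The generator emulates the structure of the four cross-compatible microarray
studies the pipeline was designed around: two rat studies, one mouse study,
and one axolotl (salamander) study, each a small injured-vs-control contrast
of log2 intensities at the early subacute time point, with 3-5 replicates per
arm.  Gene-level ground truth is planted:

* *consistent* genes shift by +effect in the injured arm of every study;
* *opposite* genes shift by +effect in rodent studies and -effect in the
  salamander study (the outgroup flip the concordance classifier looks for);
* *null* genes carry no shift.

Probesets (1-3 per gene) share their gene's signal plus independent Gaussian
noise; one probeset per gene is given an elevated baseline so the
highest-average-expression collapsing rule has a deterministic winner.
Salamander genes reach the mouse reference through a salamander->human->mouse
ortholog chain with per-hop dropout, as the axolotl annotation does in the
real data.

Everything is driven by a single integer seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from xsci.io import (
    AMINO_ACIDS,
    AlignedSequenceSet,
    ExpressionStudy,
    GeneSetCollection,
    write_aligned_fasta,
    write_annotation,
    write_expression_study,
    write_gmt,
    write_ortholog_table,
)

logger = logging.getLogger(__name__)

#: (study_id, species, n_injured, n_control) mirroring the four source studies:
#: rat clip-compression 4/4, rat transection 3/3, mouse hemisection 3/3,
#: axolotl transection 3/3.
DEFAULT_SPECIES_PLAN: tuple[tuple[str, str, int, int], ...] = (
    ("rat_clip", "rat", 4, 4),
    ("rat_transection", "rat", 3, 3),
    ("mouse_hemisection", "mouse", 3, 3),
    ("axolotl_transection", "salamander", 3, 3),
)

_ELEVATED_BASELINE = 1.5  # log2 offset of each gene's representative probeset


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-study dataset.

    Defaults reproduce the study conditions the pipeline is exercised under:
    500 genes, 10% planted consistent and 10% planted opposite, a 2.0 log2FC
    effect against 0.5 sd Gaussian noise, and a 5% per-hop ortholog dropout.
    """

    seed: int = 0
    n_genes: int = 500
    species_plan: tuple[tuple[str, str, int, int], ...] = DEFAULT_SPECIES_PLAN
    frac_consistent: float = 0.1
    frac_opposite: float = 0.1
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    ortholog_dropout: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.frac_consistent < 0 or self.frac_opposite < 0:
            raise ValueError("planted fractions must be non-negative")
        if self.frac_consistent + self.frac_opposite > 1:
            raise ValueError("frac_consistent + frac_opposite must be <= 1")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.ortholog_dropout < 1):
            raise ValueError("ortholog_dropout must lie in [0, 1)")
        if not self.species_plan:
            raise ValueError("species_plan must name at least one study")
        for study_id, species, n_inj, n_ctl in self.species_plan:
            if n_inj < 2 or n_ctl < 2:
                raise ValueError(
                    f"study {study_id!r}: fewer than 2 samples per arm "
                    "(variance undefined)"
                )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    consistent_genes: frozenset[str]
    opposite_genes: frozenset[str]
    null_genes: frozenset[str]
    enriched_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.consistent_genes, self.opposite_genes, self.null_genes]
        total = sum(len(s) for s in sets)
        union = frozenset().union(*sets)
        if len(union) != total:
            raise ValueError("planted gene classes must be pairwise disjoint")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.consistent_genes | self.opposite_genes | self.null_genes


@dataclass
class SimulatedDataset:
    """Bundle of everything the generator produces for one configuration."""

    config: SimulationConfig
    studies: list[ExpressionStudy]
    truth: PlantedTruth
    ortholog_table: pd.DataFrame
    gene_sets: GeneSetCollection
    #: per-gene winning (elevated-baseline) probeset, per study
    representative_probesets: dict[str, dict[str, str]]


def _source_gene(species: str, ref_gene: str) -> str:
    prefix = {"rat": "Rn_", "mouse": "", "salamander": "Am_", "human": "Hs_"}[species]
    return prefix + ref_gene


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate studies, truth, ortholog tables, and gene sets for *config*."""
    rng = np.random.default_rng(config.seed)
    genes = [f"Gene{i:04d}" for i in range(config.n_genes)]

    n_cons = int(round(config.frac_consistent * config.n_genes))
    n_opp = int(round(config.frac_opposite * config.n_genes))
    shuffled = list(rng.permutation(genes))
    consistent = frozenset(shuffled[:n_cons])
    opposite = frozenset(shuffled[n_cons : n_cons + n_opp])
    null = frozenset(shuffled[n_cons + n_opp :])
    effect_of = {g: config.effect_log2fc for g in consistent}
    # opposite genes flip sign in the salamander outgroup
    for g in opposite:
        effect_of[g] = config.effect_log2fc

    # per-gene baseline expression shared across studies, typical log2 range
    baseline = dict(zip(genes, rng.uniform(5.0, 9.0, size=config.n_genes)))

    studies: list[ExpressionStudy] = []
    representative: dict[str, dict[str, str]] = {}
    for study_id, species, n_inj, n_ctl in config.species_plan:
        n_ps = rng.integers(1, 4, size=config.n_genes)  # 1-3 probesets per gene
        probeset_rows = []
        ps_to_gene: dict[str, str] = {}
        reps: dict[str, str] = {}
        counter = 0
        for g, k in zip(genes, n_ps):
            offsets = rng.uniform(-0.5, 0.5, size=int(k))
            elevated = int(rng.integers(0, int(k)))
            src = _source_gene(species, g)
            for idx in range(int(k)):
                ps_id = f"{study_id}_ps{counter:05d}"
                counter += 1
                off = _ELEVATED_BASELINE if idx == elevated else float(offsets[idx])
                probeset_rows.append((ps_id, g, src, off))
                ps_to_gene[ps_id] = src
                if idx == elevated:
                    reps[g] = ps_id
        representative[study_id] = reps

        samples = [f"{study_id}_inj{i+1}" for i in range(n_inj)] + [
            f"{study_id}_ctl{i+1}" for i in range(n_ctl)
        ]
        groups = {s: ("injured" if "inj" in s.rsplit("_", 1)[1] else "control")
                  for s in samples}
        n_total = n_inj + n_ctl
        mat = np.empty((len(probeset_rows), n_total))
        for r, (_, g, _, off) in enumerate(probeset_rows):
            eff = effect_of.get(g, 0.0)
            if g in opposite and species == "salamander":
                eff = -eff
            means = np.full(n_total, baseline[g] + off)
            means[:n_inj] += eff
            mat[r] = means + rng.normal(0.0, config.noise_sd, size=n_total)
        matrix = pd.DataFrame(
            mat, index=[r[0] for r in probeset_rows], columns=samples
        )
        matrix.index.name = "probeset_id"
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                species=species,
                matrix=matrix,
                sample_groups=groups,
                probeset_to_gene=ps_to_gene,
            )
        )

    ortholog_table = _simulate_ortholog_table(config, genes, rng)
    gene_sets, enriched = _simulate_gene_sets(genes, consistent, opposite, null, rng)
    truth = PlantedTruth(
        consistent_genes=consistent,
        opposite_genes=opposite,
        null_genes=null,
        enriched_sets=enriched,
    )
    return SimulatedDataset(
        config=config,
        studies=studies,
        truth=truth,
        ortholog_table=ortholog_table,
        gene_sets=gene_sets,
        representative_probesets=representative,
    )


def _simulate_ortholog_table(
    config: SimulationConfig, genes: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Ranked ortholog entries: rat and mouse map directly to the reference;
    salamander routes salamander->human->mouse with independent per-hop
    dropout.  About 10% of entries get a rank-2 decoy candidate so the
    rank-1 rule is exercised."""
    rows = []

    def add_entry(species: str, src: str, ref: str) -> None:
        rows.append((species, src, ref, 1))
        if rng.random() < 0.1:
            decoy = f"{ref}_alt"
            rows.append((species, src, decoy, 2))

    for g in genes:
        if rng.random() >= config.ortholog_dropout:
            add_entry("rat", _source_gene("rat", g), g)
        if rng.random() >= config.ortholog_dropout:
            add_entry("mouse", _source_gene("mouse", g), g)
        # salamander chain: two hops, each with its own dropout
        if rng.random() >= config.ortholog_dropout:
            add_entry("salamander", _source_gene("salamander", g),
                      _source_gene("human", g))
        if rng.random() >= config.ortholog_dropout:
            add_entry("human", _source_gene("human", g), g)
    return pd.DataFrame(
        rows, columns=["source_species", "source_gene", "reference_gene", "rank"]
    )


def _simulate_gene_sets(
    genes: Sequence[str],
    consistent: frozenset[str],
    opposite: frozenset[str],
    null: frozenset[str],
    rng: np.random.Generator,
    n_random_sets: int = 20,
    planted_coverage: float = 0.8,
) -> tuple[GeneSetCollection, dict[str, frozenset[str]]]:
    """One planted set per non-empty truth class (covering ~80% of it, padded
    with null genes) plus random null-gene sets."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    enriched: dict[str, frozenset[str]] = {}
    null_sorted = sorted(null)
    for label, members in (("CONSISTENT", consistent), ("OPPOSITE", opposite)):
        if not members:
            continue
        members_sorted = sorted(members)
        n_take = max(1, int(round(planted_coverage * len(members_sorted))))
        take = sorted(
            rng.choice(members_sorted, size=n_take, replace=False).tolist()
        )
        pad = []
        if null_sorted:
            n_pad = min(len(null_sorted), max(2, n_take // 4))
            pad = sorted(rng.choice(null_sorted, size=n_pad, replace=False).tolist())
        term = f"SET_{label}"
        sets[term] = (f"planted {label.lower()} set", tuple(take + pad))
        enriched[term] = frozenset(take)
    for i in range(n_random_sets):
        pool = null_sorted if null_sorted else sorted(genes)
        size = int(rng.integers(5, max(6, min(30, len(pool)))))
        size = min(size, len(pool))
        members = sorted(rng.choice(pool, size=size, replace=False).tolist())
        sets[f"SET_RANDOM{i:02d}"] = (f"random set {i}", tuple(members))
    return GeneSetCollection(sets=sets, namespace="GO:BP"), enriched


def simulate_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], PlantedTruth]:
    """Generate the per-study expression matrices and the planted truth."""
    ds = simulate_dataset(config)
    return ds.studies, ds.truth


def simulate_edges(
    hub_genes: Sequence[str],
    other_genes: Sequence[str],
    seed: int = 0,
    hub_edge_prob: float = 0.3,
) -> pd.DataFrame:
    """A confidence-scored interaction edge list with a planted hub module.

    Pairs within ``hub_genes`` get high-confidence edges (0.5-1.0) with
    probability ``hub_edge_prob``; a sparse background of low-confidence
    (0.0-0.4) edges connects random pairs across all genes.  Filtering at the
    conventional 0.4 cut-off therefore isolates the planted module.
    """
    rng = np.random.default_rng(seed)
    hubs = sorted(hub_genes)
    everyone = sorted(set(hubs) | set(other_genes))
    rows = []
    for i in range(len(hubs)):
        for j in range(i + 1, len(hubs)):
            if rng.random() < hub_edge_prob:
                rows.append((hubs[i], hubs[j], float(rng.uniform(0.5, 1.0))))
    n_background = 2 * len(everyone)
    for _ in range(n_background):
        a, b = rng.choice(everyone, size=2, replace=False)
        rows.append((min(a, b), max(a, b), float(rng.uniform(0.0, 0.4))))
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    return df.drop_duplicates(["node_a", "node_b"]).reset_index(drop=True)


#: species panel of the conservation heatmaps: human reference plus the
#: commonly used SCI models
CONSERVATION_TREE = (
    "(((((human:0.05,mouse:0.04):0.01,rat:0.04):0.03,pig:0.06):0.04,"
    "(frog:0.12,salamander:0.12):0.05):0.03,zebrafish:0.20);"
)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def simulate_alignment(
    tree_newick: str,
    n_sites: int,
    subst_rate: float = 1.0,
    seed: int = 0,
) -> AlignedSequenceSet:
    """Evolve a gap-free amino-acid alignment along a Newick tree.

    Each site accumulates Poisson(branch_length * subst_rate) substitution
    events per branch; every event replaces the residue with a uniformly
    chosen *different* amino acid.  With branch lengths in expected
    substitutions per site (subst_rate = 1), the observed proportion of
    differing sites between two taxa at path distance d approaches
    1 - exp(-d), the relation the Poisson correction inverts (up to a small
    multiple-hit correction from the finite 20-letter alphabet).

    Branch lengths must be non-negative; missing lengths count as 0.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if subst_rate < 0:
        raise ValueError("subst_rate must be >= 0")
    try:
        tree = TreeNode.read(StringIO(tree_newick))
    except Exception as exc:  # skbio raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length {node.length} in tree")

    rng = np.random.default_rng(seed)
    n_aa = len(AMINO_ACIDS)
    root_seq = rng.integers(0, n_aa, size=n_sites)

    sequences: dict[int, np.ndarray] = {id(tree): root_seq}
    taxa: list[str] = []
    rows: list[str] = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    for node in tree.preorder(include_self=False):
        parent_seq = sequences[id(node.parent)]
        length = float(node.length or 0.0)
        seq = parent_seq.copy()
        n_events = rng.poisson(length * subst_rate, size=n_sites)
        for site in np.nonzero(n_events)[0]:
            for _ in range(int(n_events[site])):
                # jump to a uniformly chosen different residue
                seq[site] = (seq[site] + rng.integers(1, n_aa)) % n_aa
        sequences[id(node)] = seq
        if node.is_tip():
            taxa.append(str(node.name))
            rows.append(aa[seq].tobytes().decode())
    return AlignedSequenceSet(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------


def simulate_image(
    shape: tuple[int, int],
    true_fraction: float,
    seed: int = 0,
) -> np.ndarray:
    """An 8-bit grayscale image with an exact planted foreground fraction.

    Exactly ``round(true_fraction * n_pixels)`` pixels, at seeded random
    positions, get high intensities (180-220); the rest get low intensities
    (20-60).  Any threshold in (60, 180] therefore recovers the planted
    fraction exactly.
    """
    if not (0.0 <= true_fraction <= 1.0):
        raise ValueError("true_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_total = int(np.prod(shape))
    n_fg = int(round(true_fraction * n_total))
    flat = rng.integers(20, 61, size=n_total)
    fg_idx = rng.choice(n_total, size=n_fg, replace=False)
    flat[fg_idx] = rng.integers(180, 221, size=n_fg)
    return flat.reshape(shape).astype(np.uint8)


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write every artifact of a simulated dataset to *outdir*.

    Emits per-study expression TSVs with YAML sidecars and annotation TSVs,
    the ortholog table, the gene-set GMT, and a JSON truth file carrying the
    planted sets and the seed.  Returns a name -> path manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for study in ds.studies:
        base = outdir / study.study_id
        write_expression_study(study, f"{base}.tsv", f"{base}.yaml")
        write_annotation(study.probeset_to_gene, f"{base}.annot.tsv")
        manifest[f"expression:{study.study_id}"] = f"{base}.tsv"
        manifest[f"meta:{study.study_id}"] = f"{base}.yaml"
        manifest[f"annotation:{study.study_id}"] = f"{base}.annot.tsv"
    write_ortholog_table(ds.ortholog_table, outdir / "orthologs.tsv")
    manifest["orthologs"] = str(outdir / "orthologs.tsv")
    write_gmt(ds.gene_sets, outdir / "gene_sets.gmt")
    manifest["gene_sets"] = str(outdir / "gene_sets.gmt")
    truth = {
        "seed": ds.config.seed,
        "consistent_genes": sorted(ds.truth.consistent_genes),
        "opposite_genes": sorted(ds.truth.opposite_genes),
        "null_genes": sorted(ds.truth.null_genes),
        "enriched_sets": {
            t: sorted(m) for t, m in ds.truth.enriched_sets.items()
        },
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    manifest["truth"] = str(outdir / "truth.json")
    return manifest
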