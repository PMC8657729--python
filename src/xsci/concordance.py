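"""Cross-species ortholog harmonization and direction-of-expression classes.

Per-study gene tables are re-keyed onto a reference organism (mouse in the
original study) through ranked ortholog tables; species without a direct
mapping reach the reference through a stated chain of intermediates (the
axolotl annotation maps to human first, then human to mouse), taking the
rank-1 candidate at every hop.

Orthologs present in every species and significant (BH-adjusted p <= alpha)
in every study are classified by the signs of their per-study log2
fold-changes:

* ``consistent`` — every study shares one non-zero sign;
* ``opposite_outgroup`` — all non-outgroup studies share one non-zero sign and
  every outgroup (salamander) study carries the opposite sign;
* ``other`` — anything else, including any exactly-zero fold-change.

The three classes partition the significant set; the partition identity
n_consistent + n_opposite + n_other = n_significant is asserted on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PATTERNS = ("consistent", "opposite_outgroup", "other")


class PartitionCounts(NamedTuple):
    n_significant: int
    n_consistent: int
    n_opposite: int
    n_other: int


@dataclass
class OrthologMap:
    """Ranked ortholog candidates keyed by (source species, source gene).

    Built from a table with columns ``source_species``, ``source_gene``,
    ``reference_gene``, ``rank``.  Ranks must start at 1 and be unique per
    source gene; the rank-1 candidate is the "top ortholog" used throughout.
    """

    entries: dict[tuple[str, str], list[tuple[int, str]]] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OrthologMap":
        entries: dict[tuple[str, str], list[tuple[int, str]]] = {}
        for row in table.itertuples(index=False):
            key = (row.source_species, row.source_gene)
            entries.setdefault(key, []).append((int(row.rank), row.reference_gene))
        for key, cands in entries.items():
            cands.sort()
            ranks = [r for r, _ in cands]
            if ranks[0] != 1 or len(set(ranks)) != len(ranks):
                raise ValueError(
                    f"ortholog candidates for {key} have invalid ranks {ranks}; "
                    "ranks must start at 1 and be unique"
                )
        return cls(entries=entries)

    def top(self, species: str, gene: str) -> str | None:
        """Rank-1 reference candidate, or None if the gene has no ortholog."""
        cands = self.entries.get((species, gene))
        return cands[0][1] if cands else None

    def resolve(
        self, species: str, gene: str, chain: Mapping[str, Sequence[str]] | None = None
    ) -> str | None:
        """Resolve a source gene to the reference organism, hop by hop.

        ``chain`` maps a species to the ordered intermediate species it routes
        through (e.g. ``{"salamander": ("human",)}``: salamander ids map to
        human ids, which map to the reference).  Each hop takes the rank-1
        candidate; a dropout at any hop resolves to None.
        """
        hops = list((chain or {}).get(species, ()))
        current_species, current_gene = species, gene
        for intermediate in hops:
            nxt = self.top(current_species, current_gene)
            if nxt is None:
                return None
            current_species, current_gene = intermediate, nxt
        return self.top(current_species, current_gene)


def map_to_reference(
    tables: Mapping[str, tuple[str, pd.DataFrame]],
    ortho: OrthologMap,
    chain: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, tuple[str, pd.DataFrame]]:
    """Re-key per-study gene tables onto reference-organism orthologs.

    Parameters
    ----------
    tables : mapping study_id -> (species, gene-indexed DataFrame)
        Each DataFrame needs at least ``log2fc`` and ``p_adj`` columns.
    ortho : OrthologMap
    chain : mapping species -> intermediate species sequence
        Species that reach the reference indirectly.  A species absent from
        both the map and the chain raises.

    Returns the same structure keyed by reference gene.  When two source genes
    resolve to the same reference gene within one study, the one with the
    smaller ``p_adj`` represents it (ties by source gene id); each collision is
    logged.  Genes that fail to resolve (ortholog dropout) are dropped with a
    logged count.
    """
    out: dict[str, tuple[str, pd.DataFrame]] = {}
    chain = chain or {}
    for study_id, (species, df) in tables.items():
        if species in chain:
            missing = [
                hop for hop in chain[species]
                if not any(sp == hop for sp, _ in ortho.entries) and hop != species
            ]
            # a chained species whose intermediate never appears in the map
            # cannot be resolved at all
            if missing and not any(sp == species for sp, _ in ortho.entries):
                raise ValueError(
                    f"study {study_id!r}: no ortholog entries for chained species "
                    f"{species!r} (missing hop(s) {missing})"
                )
        has_any = any(sp == species for sp, _ in ortho.entries)
        if not has_any:
            raise ValueError(
                f"study {study_id!r}: species {species!r} absent from the "
                "ortholog map and not reachable via a chain"
            )
        resolved = pd.Series(
            [ortho.resolve(species, g, chain) for g in df.index], index=df.index
        )
        dropped = resolved.isna()
        if dropped.any():
            logger.info(
                "study %s: %d gene(s) without a resolvable reference ortholog",
                study_id, int(dropped.sum()),
            )
        kept = df[~dropped].copy()
        kept["ref_gene"] = resolved[~dropped]
        kept["source_gene"] = kept.index
        dup = kept["ref_gene"].duplicated(keep=False)
        if dup.any():
            for ref, grp in kept[dup].groupby("ref_gene"):
                logger.info(
                    "study %s: %d source genes collide on reference %s; keeping "
                    "smallest p_adj", study_id, len(grp), ref,
                )
        kept = kept.sort_values(
            ["ref_gene", "p_adj", "source_gene"], kind="mergesort"
        ).drop_duplicates("ref_gene", keep="first")
        out[study_id] = (species, kept.set_index("ref_gene").sort_index())
    return out


def _direction(log2fc: float) -> str:
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return "zero"


def classify_signs(directions: Mapping[str, str], outgroup_studies: set[str]) -> str:
    """Classify one ortholog's per-study directions (up/down/zero).

    Any ``zero`` direction yields ``other`` (no direction to compare).
    """
    values = set(directions.values())
    if "zero" in values:
        return "other"
    if len(values) == 1:
        return "consistent"
    in_dirs = {d for s, d in directions.items() if s not in outgroup_studies}
    out_dirs = {d for s, d in directions.items() if s in outgroup_studies}
    if len(in_dirs) == 1 and len(out_dirs) == 1 and in_dirs != out_dirs:
        return "opposite_outgroup"
    return "other"


def intersect_and_classify(
    tables: Mapping[str, tuple[str, pd.DataFrame]],
    outgroup: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, PartitionCounts]:
    """Intersect reference-keyed tables across species and classify directions.

    Two gates are applied in order: an ortholog must be *present* in every
    species (species-level), then *significant* (p_adj <= alpha) in every
    study (study-level).  Only significant orthologs receive a pattern.

    Returns
    -------
    (records, counts) : DataFrame indexed by ref_gene with per-study
        ``log2fc_<study>``, ``p_adj_<study>``, ``direction_<study>`` columns
        plus ``significant_all`` and ``pattern`` (empty string when not
        significant), and the partition counts over significant orthologs.
    """
    if not tables:
        empty = pd.DataFrame(columns=["significant_all", "pattern"])
        return empty, PartitionCounts(0, 0, 0, 0)
    species_of = {sid: sp for sid, (sp, _) in tables.items()}
    if outgroup not in species_of.values():
        raise ValueError(f"outgroup species {outgroup!r} has no study")
    for sid, (_, df) in tables.items():
        for col in ("log2fc", "p_adj"):
            if col not in df.columns:
                raise ValueError(f"study {sid!r}: missing required column {col!r}")

    # species-level presence gate
    species_genes: dict[str, set[str]] = {}
    for sid, (sp, df) in tables.items():
        species_genes.setdefault(sp, set()).update(df.index)
    common = sorted(set.intersection(*species_genes.values()))
    # study-level presence: a gene counted present for a species through one
    # study must still be measured in every study to be classified
    common = [
        g for g in common if all(g in df.index for _, df in tables.values())
    ]

    outgroup_studies = {sid for sid, sp in species_of.items() if sp == outgroup}
    study_ids = sorted(tables)
    rows = []
    for gene in common:
        row: dict[str, object] = {}
        directions = {}
        significant = True
        for sid in study_ids:
            df = tables[sid][1]
            fc = float(df.loc[gene, "log2fc"])
            padj = float(df.loc[gene, "p_adj"])
            row[f"log2fc_{sid}"] = fc
            row[f"p_adj_{sid}"] = padj
            row[f"direction_{sid}"] = _direction(fc)
            directions[sid] = _direction(fc)
            if padj > alpha:
                significant = False
        row["significant_all"] = significant
        row["pattern"] = (
            classify_signs(directions, outgroup_studies) if significant else ""
        )
        rows.append(row)
    records = pd.DataFrame(rows, index=pd.Index(common, name="ref_gene"))
    counts = partition_summary(records)
    logger.info(
        "concordance: %d orthologs in all species; %d significant "
        "(%d consistent, %d opposite_outgroup, %d other)",
        len(records), *counts,
    )
    return records, counts


def partition_summary(records: pd.DataFrame) -> PartitionCounts:
    """Counts of the three direction classes among significant orthologs.

    The partition identity n_consistent + n_opposite + n_other =
    n_significant is asserted (it is structural, not empirical).
    """
    if len(records) == 0 or "significant_all" not in records.columns:
        return PartitionCounts(0, 0, 0, 0)
    sig = records[records["significant_all"].astype(bool)]
    n_cons = int((sig["pattern"] == "consistent").sum())
    n_opp = int((sig["pattern"] == "opposite_outgroup").sum())
    n_other = int((sig["pattern"] == "other").sum())
    counts = PartitionCounts(len(sig), n_cons, n_opp, n_other)
    assert counts.n_consistent + counts.n_opposite + counts.n_other == counts.n_significant
    return counts
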