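"""Readers and writers for every on-disk format the pipeline touches.

Formats (all plain text, UTF-8, tab-separated, '.' decimal):

* expression matrix — TSV, first column ``probeset_id``, remaining columns one
  per sample, plus a YAML sidecar naming the study, species, and per-sample
  group labels (``injured`` / ``control``);
* probeset annotation — TSV with columns ``probeset_id``, ``gene_symbol``;
* ortholog table — TSV with columns ``source_species``, ``source_gene``,
  ``reference_gene``, ``rank``;
* gene sets — GMT (term, description, members...);
* alignments — FASTA of equal-length amino-acid rows;
* interaction edges — TSV with columns ``node_a``, ``node_b``, ``confidence``.

Values are assumed to be already normalized log2 intensities (RMA/gcRMA-style);
no normalization is performed here.  Readers validate strictly and never drop
rows silently: every skip is logged with a count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_SPECIES = {"rat", "mouse", "salamander", "human", "other"}
VALID_GROUPS = {"injured", "control"}
VALID_NAMESPACES = {"GO:MF", "GO:BP", "GO:CC", "KEGG"}

# 20 canonical residues plus alignment gap '-' and ambiguity 'X'
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "-X")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix with its sample groups.

    Parameters
    ----------
    study_id : str
        Stable identifier, e.g. a GEO-style accession.
    species : str
        One of ``rat``, ``mouse``, ``salamander``, ``other``.
    matrix : pandas.DataFrame
        Probesets (rows, unique index) by samples (columns); log2 intensities.
    sample_groups : Mapping[str, str]
        Per-sample arm label, ``injured`` or ``control``.
    probeset_to_gene : Mapping[str, str]
        Probeset to gene-symbol annotation; probesets without an entry are
        treated as unmapped downstream.
    """

    study_id: str
    species: str
    matrix: pd.DataFrame
    sample_groups: Mapping[str, str]
    probeset_to_gene: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(
                f"study {self.study_id!r}: unknown species {self.species!r}"
            )
        idx = self.matrix.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(
                f"study {self.study_id!r}: duplicate probeset ids {dupes}"
            )
        vals = self.matrix.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float, copy=False)).all():
            raise ValueError(f"study {self.study_id!r}: non-finite expression values")
        missing = [s for s in self.matrix.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: samples without group labels: {missing}"
            )
        bad = {
            s: g
            for s, g in self.sample_groups.items()
            if s in self.matrix.columns and g not in VALID_GROUPS
        }
        if bad:
            raise ValueError(f"study {self.study_id!r}: invalid group labels {bad}")
        for grp in sorted(VALID_GROUPS):
            n = len(self.samples(grp))
            if n < 2:
                raise ValueError(
                    f"study {self.study_id!r}: group {grp!r} has {n} sample(s); "
                    "at least 2 per arm are required (variance undefined otherwise)"
                )

    def samples(self, group: str) -> list[str]:
        """Sample names belonging to *group*, in matrix column order."""
        return [s for s in self.matrix.columns if self.sample_groups[s] == group]


@dataclass
class GeneSetCollection:
    """A GMT-style collection of gene sets within one namespace."""

    sets: dict[str, tuple[str, tuple[str, ...]]]
    namespace: str = "GO:BP"

    def __post_init__(self) -> None:
        if self.namespace not in VALID_NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {term!r} has duplicate members")

    def members(self, term: str) -> frozenset[str]:
        return frozenset(self.sets[term][1])


@dataclass
class AlignedSequenceSet:
    """An amino-acid multiple alignment: equal-length rows over AA + '-' + 'X'."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows have different lengths")
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for name, row in zip(self.taxa, self.rows):
            bad = set(row) - _ALLOWED_RESIDUES
            if bad:
                raise ValueError(f"illegal residue(s) {sorted(bad)} in {name!r}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# expression matrix + YAML sidecar
# ---------------------------------------------------------------------------


def read_expression_study(path: str | Path, meta: str | Path | Mapping) -> ExpressionStudy:
    """Read an expression TSV plus its YAML sidecar into an ExpressionStudy.

    ``meta`` is either the sidecar path or an already-parsed mapping with keys
    ``study_id``, ``species``, and ``sample_groups``.
    """
    path = Path(path)
    if not isinstance(meta, Mapping):
        with open(meta, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.name is None or mat.index.has_duplicates:
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"{path}: duplicate probeset id(s) {dupes}")
    non_numeric = [c for c in mat.columns if not np.issubdtype(mat[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric cells in column(s) {non_numeric}")
    mat.index = mat.index.astype(str)
    return ExpressionStudy(
        study_id=str(meta["study_id"]),
        species=str(meta["species"]),
        matrix=mat,
        sample_groups=dict(meta["sample_groups"]),
        probeset_to_gene=dict(meta.get("probeset_to_gene", {})),
    )


def write_expression_study(study: ExpressionStudy, path: str | Path,
                           meta_path: str | Path | None = None) -> None:
    """Write the matrix TSV and (optionally) the YAML sidecar."""
    path = Path(path)
    mat = study.matrix.copy()
    mat.index.name = "probeset_id"
    mat.to_csv(path, sep="\t", lineterminator="\n", float_format="%.6f")
    if meta_path is not None:
        meta = {
            "study_id": study.study_id,
            "species": study.species,
            "sample_groups": dict(study.sample_groups),
        }
        with open(meta_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation and ortholog tables
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a probeset→gene TSV (columns probeset_id, gene_symbol).

    Rows with an empty gene symbol are skipped (logged with a count): these are
    unannotated probesets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["probeset_id", "gene_symbol"]:
        raise ValueError(
            f"{path}: expected columns probeset_id, gene_symbol; got {list(df.columns)}"
        )
    blank = df["gene_symbol"] == ""
    if blank.any():
        logger.info("%s: skipped %d unannotated probeset(s)", path, int(blank.sum()))
    df = df[~blank]
    if df["probeset_id"].duplicated().any():
        dupes = df.loc[df["probeset_id"].duplicated(), "probeset_id"].tolist()
        raise ValueError(f"{path}: duplicate probeset id(s) {dupes}")
    return dict(zip(df["probeset_id"], df["gene_symbol"]))


def write_annotation(mapping: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(mapping.items()), columns=["probeset_id", "gene_symbol"]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read an ortholog TSV (source_species, source_gene, reference_gene, rank)."""
    df = pd.read_csv(path, sep="\t", dtype={"rank": int}, keep_default_na=False)
    required = ["source_species", "source_gene", "reference_gene", "rank"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    if (df["rank"] < 1).any():
        raise ValueError(f"{path}: ranks must start at 1")
    return df


def write_ortholog_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, namespace: str = "GO:BP") -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set (term, description, members...).

    Blank lines are skipped (logged).  A set with zero members is an error.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    n_blank = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                n_blank += 1
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no members"
                )
            term, desc, members = parts[0], parts[1], tuple(p for p in parts[2:] if p)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {term!r} has no members")
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, members)
    if n_blank:
        logger.info("%s: skipped %d blank line(s)", path, n_blank)
    return GeneSetCollection(sets=sets, namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# aligned FASTA
# ---------------------------------------------------------------------------


def read_aligned_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned amino-acid FASTA; residues are case-normalized to upper."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: an alignment needs at least 2 records")
    return AlignedSequenceSet(
        taxa=[r.id for r in records], rows=[str(r.seq) for r in records]
    )


def write_aligned_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# interaction edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an undirected interaction edge TSV (node_a, node_b, confidence).

    Self-loops are dropped (logged); duplicate undirected edges are collapsed
    to their maximum confidence (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    required = ["node_a", "node_b", "confidence"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    return normalize_edges(df, source=str(path))


def normalize_edges(df: pd.DataFrame, source: str = "edges") -> pd.DataFrame:
    """Validate confidences, drop self-loops, collapse duplicate undirected edges."""
    conf = df["confidence"].astype(float)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError(f"{source}: confidence values must lie in [0, 1]")
    df = df.assign(confidence=conf)
    loops = df["node_a"] == df["node_b"]
    if loops.any():
        logger.info("%s: dropped %d self-loop(s)", source, int(loops.sum()))
        df = df[~loops]
    key = df.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
    df = df.assign(_key=key)
    n_before = len(df)
    df = (
        df.groupby("_key", as_index=False)
        .agg(confidence=("confidence", "max"))
        .assign(
            node_a=lambda d: d["_key"].str[0],
            node_b=lambda d: d["_key"].str[1],
        )[["node_a", "node_b", "confidence"]]
        .sort_values(["node_a", "node_b"], ignore_index=True)
    )
    if len(df) < n_before:
        logger.info(
            "%s: collapsed %d duplicate undirected edge(s) to max confidence",
            source, n_before - len(df),
        )
    return df


def write_edge_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
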