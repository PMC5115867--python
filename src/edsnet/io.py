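"""TSV / FASTA / newick readers and writers and the pipeline config.

All tabular formats are headered TSV; readers validate that every row has
the header's column count and report the offending line number otherwise.
Genomic intervals in BED-like inputs are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .phylogenomics import SimilarityHit

__all__ = [
    "PipelineConfig",
    "read_tsv",
    "read_counts",
    "read_metadata",
    "read_hits",
    "read_te_table",
    "write_fasta_pairs",
    "read_fasta_pairs",
]


class RaggedRowError(ValueError):
    pass


def read_tsv(path: Union[str, Path], index_col: Optional[int] = None
             ) -> pd.DataFrame:
    """Headered TSV reader that rejects ragged rows with line numbers."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        n_cols = len(header.split("\t"))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != n_cols:
                raise RaggedRowError(
                    f"{path}: line {lineno} has a different column count "
                    f"than the header ({n_cols})")
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_counts(path) -> Tuple[pd.DataFrame, Optional[pd.Series]]:
    """Counts TSV: gene id index, optional ``length`` column, the rest
    sample columns of nonnegative integers."""
    df = read_tsv(path, index_col=0)
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length")
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if not (df.to_numpy() == df.to_numpy().astype(int)).all():
        raise ValueError("counts must be integral")
    return df.astype(int), lengths


def read_metadata(path) -> pd.DataFrame:
    meta = read_tsv(path, index_col=0)
    required = {"species", "treatment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns {sorted(missing)}")
    key = meta[["species", "treatment", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (species, treatment, replicate) rows")
    return meta


def write_counts(path, counts: pd.DataFrame,
                 lengths: Optional[pd.Series] = None) -> None:
    out = counts.copy()
    if lengths is not None:
        out.insert(0, "length", lengths.reindex(counts.index))
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


BLAST_COLUMNS = [
    "query", "subject", "identity_pct", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "coverage",
]


def read_hits(path) -> List[SimilarityHit]:
    """13-column BLAST-tabular-like hits (12 standard columns plus a
    query-coverage fraction); identity is a percentage."""
    df = read_tsv(path)
    missing = set(BLAST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hits table lacks columns {sorted(missing)}")
    hits = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hits.append(SimilarityHit(
                query=str(row.query), subject=str(row.subject),
                evalue=float(row.evalue), length=int(row.length),
                coverage=float(row.coverage),
                identity=float(row.identity_pct) / 100.0,
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hits(path, hits: Sequence[SimilarityHit]) -> None:
    rows = []
    for h in hits:
        rows.append((h.query, h.subject, h.identity * 100.0, h.length,
                     0, 0, 1, h.length, 1, h.length, h.evalue, 0.0,
                     h.coverage))
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_te_table(path) -> pd.DataFrame:
    """BED-like TE-insertion table.

    Either distance form (columns ``gene``, ``family``, ``distance``) or
    interval form (``chrom start end family gene gene_start gene_strand``,
    0-based half-open) converted to strand-aware upstream distances from
    the transcription start.
    """
    df = read_tsv(path)
    if {"gene", "family", "distance"} <= set(df.columns):
        out = df[["gene", "family", "distance"]].copy()
    elif {"chrom", "start", "end", "family", "gene", "gene_start",
          "gene_strand"} <= set(df.columns):
        dist = []
        for row in df.itertuples(index=False):
            if row.gene_strand == "+":
                d = row.gene_start - row.end  # TE fully upstream on +
            else:
                d = row.start - row.gene_start
            dist.append(max(int(d), 0))
        out = pd.DataFrame({"gene": df["gene"], "family": df["family"],
                            "distance": dist})
    else:
        raise ValueError("unrecognized TE table columns")
    if (out["distance"] < 0).any():
        raise ValueError("negative upstream distance")
    return out


def write_fasta_pairs(path, pairs: Sequence[Tuple[str, str]]) -> None:
    """Write codon pairs as FASTA with ids ``pair<i>_a`` / ``pair<i>_b``."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for i, (s1, s2) in enumerate(pairs):
        records.append(SeqRecord(Seq(s1), id=f"pair{i}_a", description=""))
        records.append(SeqRecord(Seq(s2), id=f"pair{i}_b", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta_pairs(path) -> List[Tuple[str, str]]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError("paired FASTA must hold an even record count")
    return [(str(records[i].seq), str(records[i + 1].seq))
            for i in range(0, len(records), 2)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Every stage parameter with its default; round-trips through YAML."""

    seed: int = 1
    outdir: str = "eds_run"
    focal_species: str = "N_attenuata"
    wgt_branch: str = "SOL_WGT_STEM"

    # synthetic data
    n_genes: int = 2000
    module_size: int = 100
    effect_log2: float = 2.0
    batch_sd: float = 0.5
    dispersion: float = 0.1
    n_families: int = 200
    dup_rate: float = 0.1
    wgt_retention_prob: float = 0.25
    loss_prob: float = 0.02
    n_codon_pairs: int = 100
    n_codons: int = 300
    sim_omega: float = 0.2
    sim_ks: float = 0.3

    # expression / DE
    fpkm_min: float = 5.0
    fpkm_min_samples: int = 3
    fc_threshold: float = 1.5
    alpha: float = 0.05

    # network
    top_k: int = 5000
    power: Optional[int] = 6          # None = pick by scale-free fit
    r2_target: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.98
    kme_core: float = 0.75
    hub_fraction: float = 0.05
    edge_cutoff: float = 0.15
    n_perm: int = 200

    # phylogenomics
    support_min: float = 0.9
    e_max: float = 1e-20
    len_min: int = 60
    cov_min: float = 0.60
    id_min: float = 0.50
    inflation: float = 2.0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
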