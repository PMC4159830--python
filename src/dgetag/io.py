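"""File formats and configuration.

FASTA via Biopython; reads as a minimal FASTQ dialect (constant quality "I")
or plain one-read-per-line text, gzip accepted transparently; all tables as
TSV with headers and 6-significant-digit floats; pipeline configuration as a
YAML file.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SyntheticGene

_VALID_BASES = set("ACGTN")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a reference FASTA into (record_id, uppercase sequence) pairs.

    CRLF and LF files parse identically; non-ACGTN characters are an input
    error naming the record.
    """
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"record {rec.id!r}: invalid characters {sorted(bad)}"
                )
            if not rec.id:
                raise ValueError("malformed FASTA header: empty record id")
            records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]] | Sequence[SyntheticGene], path) -> None:
    recs = []
    for item in records:
        if isinstance(item, SyntheticGene):
            recs.append(SeqRecord(Seq(item.seq), id=item.transcript_id, description=""))
        else:
            name, seq = item
            recs.append(SeqRecord(Seq(seq), id=name, description=""))
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_gene_map(path) -> dict[str, str]:
    """TSV with columns transcript_id, gene_id -> transcript -> gene dict."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: gene map missing column {col!r}")
    return dict(zip(df["transcript_id"].astype(str), df["gene_id"].astype(str)))


def write_gene_map(genes: Sequence[SyntheticGene], path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [g.transcript_id for g in genes],
            "gene_id": [g.gene_id for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_reads(path) -> Iterator[str]:
    """Yield raw reads from FASTQ (4-line records) or one-read-per-line text."""
    with _open_text(path) as fh:
        first = fh.readline()
        if not first:
            return
        if first.startswith("@"):
            # FASTQ dialect: @name / seq / + / qual
            while True:
                seq = fh.readline()
                if not seq:
                    break
                yield seq.strip()
                fh.readline()  # +
                fh.readline()  # qualities
                header = fh.readline()
                if not header:
                    break
                if not header.startswith("@"):
                    raise ValueError(f"{path}: malformed FASTQ record near {header!r}")
        else:
            yield first.strip()
            for line in fh:
                line = line.strip()
                if line:
                    yield line


def write_fastq(reads: Iterable[str], path, prefix: str = "read") -> None:
    with _open_text(path, "wt") as fh:
        for i, read in enumerate(reads, start=1):
            fh.write(f"@{prefix}{i}\n{read}\n+\n{'I' * len(read)}\n")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end trio pipeline.

    Exactly one of ``reads`` (paths for libraries P, M, F1) or ``simulation``
    (synthetic-data block) must be supplied. Thresholds default to the
    study's rule: FDR <= 0.001 and |log2 ratio| >= 1.
    """

    reference_fasta: str | None = None
    gene_map: str | None = None
    reads: dict[str, str] | None = None
    simulation: dict | None = None
    go_annotation: str | None = None
    pathway_annotation: str | None = None
    pav_list: str | None = None
    adaptor3: str = "TCGTATGCCGTCTT"
    fdr_threshold: float = 0.001
    lfc_threshold: float = 1.0
    midparent_lfc_threshold: float = 0.0
    presence_min_count: int = 1
    max_mismatch: int = 1
    pseudo_tags: float = 0.5
    enrichment_lambda: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.reads is None) == (self.simulation is None):
            raise ValueError("exactly one of 'reads' or 'simulation' must be supplied")
        if self.reads is not None:
            missing = {"P", "M", "F1"} - set(self.reads)
            if missing:
                raise ValueError(f"reads block missing libraries: {sorted(missing)}")
            if self.reference_fasta is None or self.gene_map is None:
                raise ValueError("reads mode requires reference_fasta and gene_map")
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if self.lfc_threshold < 0 or self.midparent_lfc_threshold < 0:
            raise ValueError("log2-ratio thresholds must be >= 0")
        if self.presence_min_count < 1:
            raise ValueError("presence_min_count must be >= 1")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if not 0 <= self.enrichment_lambda < 1:
            raise ValueError("enrichment_lambda must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with _open_text(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
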