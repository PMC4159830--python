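"""Tag cleaning, the virtual CATG+17 library, mapping, TPM and accounting.

The assay's unit of observation is a 21-nt tag: "CATG" plus the 17 nt that
follow it on a transcript. Raw 35-bp reads are trimmed and filtered into
clean tags; a virtual library indexes every CATG+17 sequence of the reference
(both strands); clean tags are mapped with at most one mismatch; gene-level
expression is the sum of sense-strand unambiguous tag copies, normalized to
TPM (tags per million clean tags).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simulate import CATG, TAG_LEN, reverse_complement

SENSE = "sense"
ANTISENSE = "antisense"

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"


@dataclass
class CleanTagSet:
    """Multiset of clean 21-mer tags plus the cleaning report.

    ``clean_total`` is the library size N used for TPM and for the exact
    count test; ``report`` counts every rejection class.
    """

    counts: Counter = field(default_factory=Counter)
    raw_total: int = 0
    report: dict = field(default_factory=dict)

    @property
    def clean_total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_count(self) -> int:
        return len(self.counts)


def extract_clean_tags(reads: Iterable[str], adaptor3: str) -> CleanTagSet:
    """Trim the 3' adaptor and filter reads into clean tags.

    Each read is cut at the first occurrence of ``adaptor3`` (truncated to 21
    nt when the adaptor is not found). The remainder is kept iff it is exactly
    21 nt, begins with CATG and contains no N. Rejection classes: ``empty_tag``
    (adaptor at position 0), ``contains_n``, ``bad_length`` (too long or too
    short after trimming), ``no_catg_prefix``.
    """
    if not adaptor3:
        raise ValueError("adaptor3 must be a non-empty sequence")
    tags: Counter = Counter()
    report = {
        "raw_total": 0,
        "empty_tag": 0,
        "bad_length": 0,
        "contains_n": 0,
        "no_catg_prefix": 0,
        "clean_total": 0,
    }
    for read in reads:
        read = read.strip().upper()
        if not read:
            continue
        report["raw_total"] += 1
        cut = read.find(adaptor3)
        if cut == 0:
            report["empty_tag"] += 1
            continue
        tag = read[:cut] if cut != -1 else read[:TAG_LEN]
        if len(tag) != TAG_LEN:
            report["bad_length"] += 1
            continue
        if "N" in tag:
            report["contains_n"] += 1
            continue
        if not tag.startswith(CATG):
            report["no_catg_prefix"] += 1
            continue
        tags[tag] += 1
    report["clean_total"] = sum(tags.values())
    report["distinct"] = len(tags)
    return CleanTagSet(counts=tags, raw_total=report["raw_total"], report=report)


class TagHit(NamedTuple):
    gene_id: str
    transcript_id: str
    pos: int  # 0-based start of CATG on the indexed strand
    strand: str


class TagLibrary:
    """Virtual library: every CATG+17 21-mer of the reference, both strands.

    Antisense entries come from scanning the reverse complement of each
    transcript; their positions are 0-based on that reverse-complement
    sequence. A key hit by several genes is ambiguous; hits on both strands
    of one gene keep the key unambiguous.
    """

    def __init__(self) -> None:
        self.hits: dict[str, list[TagHit]] = {}

    def __len__(self) -> int:
        return len(self.hits)

    def __contains__(self, tag: str) -> bool:
        return tag in self.hits

    def genes(self, tag: str) -> set[str]:
        return {h.gene_id for h in self.hits.get(tag, ())}

    def is_unambiguous(self, tag: str) -> bool:
        return len(self.genes(tag)) == 1

    def _add_strand(self, gene_id: str, transcript_id: str, seq: str, strand: str) -> None:
        pos = seq.find(CATG)
        while pos != -1:
            if pos + TAG_LEN <= len(seq):
                key = seq[pos : pos + TAG_LEN]
                self.hits.setdefault(key, []).append(
                    TagHit(gene_id, transcript_id, pos, strand)
                )
            pos = seq.find(CATG, pos + 1)


def build_virtual_library(
    transcripts: Iterable[tuple[str, str]] | Mapping[str, str],
    gene_map: Mapping[str, str],
) -> TagLibrary:
    """Index all CATG+17 tags of the reference transcripts, both strands.

    ``transcripts`` yields (transcript_id, sequence); ``gene_map`` maps
    transcript_id -> gene_id. A transcript missing from the gene map is an
    input error naming the record.
    """
    lib = TagLibrary()
    items = transcripts.items() if isinstance(transcripts, Mapping) else transcripts
    for transcript_id, seq in items:
        if transcript_id not in gene_map:
            raise KeyError(f"transcript {transcript_id!r} missing from gene map")
        gene_id = gene_map[transcript_id]
        seq = seq.upper()
        lib._add_strand(gene_id, transcript_id, seq, SENSE)
        lib._add_strand(gene_id, transcript_id, reverse_complement(seq), ANTISENSE)
    return lib


def _hamming1_neighbors(tag: str) -> Iterator[str]:
    for i, c in enumerate(tag):
        for b in "ACGT":
            if b != c:
                yield tag[:i] + b + tag[i + 1 :]


@dataclass
class MappingResult:
    """Per-tag assignments plus gene-level counts for one library."""

    assignments: pd.DataFrame  # tag, copies, status, tier, gene_id, strand
    sense_counts: pd.Series  # gene_id -> sense unambiguous tag copies
    antisense_counts: pd.Series
    summary: dict


def map_tags(
    tags: CleanTagSet,
    library: TagLibrary,
    max_mismatch: int = 1,
) -> MappingResult:
    """Map clean tags to genes, exact matches first, then one mismatch.

    Tier 1 is an exact key lookup; tier 2 (taken only when tier 1 is empty)
    is the union of hits over all keys at Hamming distance 1. At the accepted
    tier, one hit gene makes the tag unambiguous, several make it ambiguous
    (mapped but excluded from gene counts), none make it unknown. A tag with
    any sense-strand hit counts toward its gene's sense (expression) count;
    purely antisense tags are tallied separately for the strand report.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    rows = []
    sense_counts: Counter = Counter()
    antisense_counts: Counter = Counter()
    totals = {
        UNAMBIGUOUS: [0, 0],  # copies, distinct
        AMBIGUOUS: [0, 0],
        UNKNOWN: [0, 0],
    }
    for tag, copies in tags.counts.items():
        hits = library.hits.get(tag)
        tier = 0
        if not hits and max_mismatch == 1:
            tier = 1
            hits = []
            for neighbor in _hamming1_neighbors(tag):
                hits.extend(library.hits.get(neighbor, ()))
        genes = {h.gene_id for h in hits} if hits else set()
        if not genes:
            status, gene_id, strand = UNKNOWN, None, None
            tier = -1
        elif len(genes) > 1:
            status, gene_id, strand = AMBIGUOUS, None, None
        else:
            status = UNAMBIGUOUS
            gene_id = next(iter(genes))
            strand = SENSE if any(h.strand == SENSE for h in hits) else ANTISENSE
            if strand == SENSE:
                sense_counts[gene_id] += copies
            else:
                antisense_counts[gene_id] += copies
        totals[status][0] += copies
        totals[status][1] += 1
        rows.append((tag, copies, status, tier, gene_id, strand))

    assignments = pd.DataFrame(
        rows, columns=["tag", "copies", "status", "tier", "gene_id", "strand"]
    )
    summary = {
        "clean_total": tags.clean_total,
        "distinct": tags.distinct_count,
        "all_mapped_total": totals[UNAMBIGUOUS][0] + totals[AMBIGUOUS][0],
        "all_mapped_distinct": totals[UNAMBIGUOUS][1] + totals[AMBIGUOUS][1],
        "unambiguous_total": totals[UNAMBIGUOUS][0],
        "unambiguous_distinct": totals[UNAMBIGUOUS][1],
        "ambiguous_total": totals[AMBIGUOUS][0],
        "ambiguous_distinct": totals[AMBIGUOUS][1],
        "unknown_total": totals[UNKNOWN][0],
        "unknown_distinct": totals[UNKNOWN][1],
    }
    return MappingResult(
        assignments=assignments,
        sense_counts=pd.Series(sense_counts, dtype=np.int64).sort_index(),
        antisense_counts=pd.Series(antisense_counts, dtype=np.int64).sort_index(),
        summary=summary,
    )


def tpm_normalize(counts: pd.Series | np.ndarray, clean_total: int):
    """TPM = count / clean_total * 1e6."""
    if clean_total < 1:
        raise ValueError("clean_total must be >= 1")
    return counts / clean_total * 1e6


class ExpressionTable:
    """Per-gene unambiguous sense counts and TPM for a set of libraries."""

    def __init__(
        self,
        counts: pd.DataFrame,
        clean_totals: Mapping[str, int],
        antisense_counts: pd.DataFrame | None = None,
        mapping_summaries: Mapping[str, dict] | None = None,
    ) -> None:
        missing = set(counts.columns) - set(clean_totals)
        if missing:
            raise ValueError(f"no clean totals for libraries: {sorted(missing)}")
        self.counts = counts.astype(np.int64)
        self.clean_totals = dict(clean_totals)
        self.antisense_counts = antisense_counts
        self.mapping_summaries = dict(mapping_summaries or {})

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tpm(self) -> pd.DataFrame:
        return self.counts / pd.Series(self.clean_totals) * 1e6

    def expressed(self, library: str, min_count: int = 1) -> set[str]:
        col = self.counts[library]
        return set(col.index[col >= min_count])

    def expressed_collectively(self, min_count: int = 1) -> set[str]:
        """Union of genes detected in any library (sense unambiguous tags)."""
        out: set[str] = set()
        for lib in self.libraries:
            out |= self.expressed(lib, min_count)
        return out

    def expressed_in_all(self, min_count: int = 1) -> set[str]:
        sets = [self.expressed(lib, min_count) for lib in self.libraries]
        return set.intersection(*sets) if sets else set()

    @classmethod
    def from_mappings(
        cls, mappings: Mapping[str, MappingResult], gene_ids: Sequence[str]
    ) -> "ExpressionTable":
        index = pd.Index(gene_ids, name="gene_id")
        counts = pd.DataFrame(
            {lib: m.sense_counts.reindex(index, fill_value=0) for lib, m in mappings.items()},
            index=index,
        ).fillna(0)
        anti = pd.DataFrame(
            {
                lib: m.antisense_counts.reindex(index, fill_value=0)
                for lib, m in mappings.items()
            },
            index=index,
        ).fillna(0)
        return cls(
            counts=counts,
            clean_totals={lib: m.summary["clean_total"] for lib, m in mappings.items()},
            antisense_counts=anti.astype(np.int64),
            mapping_summaries={lib: m.summary for lib, m in mappings.items()},
        )

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        for lib in self.libraries:
            df[f"tpm_{lib}"] = self.tpm[lib]
        header = "#clean_totals\t" + "\t".join(
            f"{lib}={self.clean_totals[lib]}" for lib in self.libraries
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#clean_totals":
                raise ValueError(f"{path}: missing #clean_totals header line")
            totals = dict(item.split("=") for item in header[1:])
            totals = {k: int(v) for k, v in totals.items()}
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        counts = df[list(totals)]
        return cls(counts=counts, clean_totals=totals)


def saturation_curve(
    tag_stream: Iterable[str],
    library: TagLibrary,
    step: int = 100_000,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Distinct tags seen and genes detected as sequencing depth grows.

    Consumes tags in stream order and records (tags processed, distinct tags,
    genes detected by unambiguous mapping) every ``step`` tags and at the end.
    Both curves are monotone nondecreasing.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    seen: set[str] = set()
    genes: set[str] = set()
    cache: dict[str, str | None] = {}
    rows = []
    n = 0
    for tag in tag_stream:
        n += 1
        if tag not in seen:
            seen.add(tag)
            if tag not in cache:
                hits = library.hits.get(tag)
                if not hits and max_mismatch == 1:
                    hits = []
                    for neighbor in _hamming1_neighbors(tag):
                        hits.extend(library.hits.get(neighbor, ()))
                hit_genes = {h.gene_id for h in hits} if hits else set()
                cache[tag] = next(iter(hit_genes)) if len(hit_genes) == 1 else None
            if cache[tag] is not None:
                genes.add(cache[tag])
        if n % step == 0:
            rows.append((n, len(seen), len(genes)))
    if not rows or rows[-1][0] != n:
        rows.append((n, len(seen), len(genes)))
    return pd.DataFrame(rows, columns=["tags_processed", "distinct_tags", "genes_detected"])


def strand_report(mappings: Mapping[str, MappingResult] | MappingResult) -> dict:
    """Genes detected on the sense strand, the antisense strand, or both.

    The ratio is (#genes with >= 1 sense tag) / (#genes with >= 1 antisense
    tag), reported as None when no gene has an antisense tag. Accepts one
    MappingResult or a {library: MappingResult} mapping (union over libraries).
    """
    if isinstance(mappings, MappingResult):
        mappings = {"library": mappings}
    sense_genes: set[str] = set()
    antisense_genes: set[str] = set()
    for m in mappings.values():
        sense_genes |= set(m.sense_counts.index[m.sense_counts > 0])
        antisense_genes |= set(m.antisense_counts.index[m.antisense_counts > 0])
    ratio = len(sense_genes) / len(antisense_genes) if antisense_genes else None
    return {
        "sense_genes": len(sense_genes),
        "antisense_genes": len(antisense_genes),
        "both_strands": len(sense_genes & antisense_genes),
        "sense_antisense_ratio": ratio,
    }
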