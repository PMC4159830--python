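"""Synthetic DGE tag-seq data with full ground truth.

Emulates the study design of a three-library trio experiment: two inbred
parents (P, a B73-like line; M, a Mo17-like line) and their F1 hybrid, each
sequenced as an NlaIII/MmeI digital gene-expression library of ~4.2 million
35-bp reads. Each read carries a 21-nt "CATG"+17 tag from the 3'-most CATG
site of a transcript, followed by adaptor sequence.

Every stochastic operation takes an explicit integer seed; there is no global
random state, and outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TAG_LEN = 21
CATG = "CATG"
READ_LEN = 35

#: 3' adaptor ligated downstream of the tag (Illumina GEX adaptor 2 prefix);
#: the 14 nt that fit in a 35-bp read after the 21-nt tag. Contains no CATG.
DEFAULT_ADAPTOR = "TCGTATGCCGTCTT"

GENOTYPES = ("P", "M", "F1")

#: Gene-action modes the simulator can assign.
MODES = (
    "additive",
    "HPD",
    "LPD",
    "ODO",
    "UDO",
    "other",
    "absent_in_P",
    "absent_in_M",
    "absent_in_both_parents",
)

#: Default mode mixture: the proportions of the six gene-action classes seen
#: in the maize ear trio among differential genes (additive ~9%, dominance
#: classes dominating, over/under-dominance present, a small "other" rest).
DEFAULT_MODE_PROPORTIONS = {
    "additive": 0.09,
    "HPD": 0.23,
    "LPD": 0.30,
    "ODO": 0.13,
    "UDO": 0.23,
    "other": 0.02,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGene:
    """A simulated gene with a single transcript.

    ``canonical_tag`` is the CATG+17 21-mer at the 3'-most CATG of the sense
    strand that has a full 17-nt overhang; genes without such a site are
    undetectable by the assay. ``antisense_tag`` is the analogous tag on the
    reverse complement (used for antisense reads), if one exists.
    """

    gene_id: str
    transcript_id: str
    seq: str
    canonical_tag: str | None
    n_catg_sites: int
    antisense_tag: str | None

    @property
    def detectable(self) -> bool:
        return self.canonical_tag is not None


def _find_canonical_tag(seq: str) -> str | None:
    """3'-most CATG with >= 17 nt downstream, as a 21-mer, else None."""
    pos = seq.rfind(CATG, 0, len(seq) - 17)
    if pos == -1:
        return None
    return seq[pos : pos + TAG_LEN]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _strip_catg(rng: np.random.Generator, arr: np.ndarray) -> np.ndarray:
    """Remove every CATG occurrence by point repair (rejection with repair)."""
    seq = arr.tobytes().decode()
    while True:
        pos = seq.find(CATG)
        if pos == -1:
            return np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        i = pos + int(rng.integers(0, 4))
        old = seq[i]
        alternatives = [b for b in "ACGT" if b != old]
        seq = seq[:i] + alternatives[int(rng.integers(0, 3))] + seq[i + 1 :]


def simulate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 3000),
    gc: float = 0.45,
    frac_no_catg: float = 0.0,
    seed: int = 0,
) -> list[SyntheticGene]:
    """Generate a reference transcriptome of single-transcript genes.

    Approximately ``frac_no_catg`` of genes (independent Bernoulli draws) are
    constructed to contain no CATG site at all and are therefore invisible to
    the assay. Every other gene is guaranteed a canonical tag (a CATG site
    with a full 17-nt overhang is planted if the random draw lacks one).
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= frac_no_catg < 1:
        raise ValueError("frac_no_catg must be in [0, 1)")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"impossible GC content {gc}")
    lo, hi = length_range
    if lo > hi or lo < TAG_LEN:
        raise ValueError(f"impossible length range {length_range}")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes: list[SyntheticGene] = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        arr = _random_seq(rng, length, gc)
        no_catg = rng.random() < frac_no_catg
        if no_catg:
            arr = _strip_catg(rng, arr)
            seq = arr.tobytes().decode()
        else:
            seq = arr.tobytes().decode()
            if _find_canonical_tag(seq) is None:
                pos = int(rng.integers(0, length - TAG_LEN + 1))
                arr[pos : pos + 4] = _BASES[[1, 0, 3, 2]]  # "CATG"
                seq = arr.tobytes().decode()
        gid = f"GENE{i + 1:0{width}d}"
        genes.append(
            SyntheticGene(
                gene_id=gid,
                transcript_id=gid + "_T01",
                seq=seq,
                canonical_tag=_find_canonical_tag(seq),
                n_catg_sites=seq.count(CATG),
                antisense_tag=_find_canonical_tag(reverse_complement(seq)),
            )
        )
    return genes


def _mode_levels(
    mode: str, base: float, high_first: bool, fold: float
) -> tuple[float, float, float]:
    """True (P, M, F1) expression levels for one gene before rescaling."""
    hi, lo = base * fold, base
    p, m = (hi, lo) if high_first else (lo, hi)
    if mode == "additive":
        return p, m, (p + m) / 2.0
    if mode == "HPD":
        return p, m, max(p, m)
    if mode == "LPD":
        return p, m, min(p, m)
    if mode == "ODO":
        return base, base, base * fold
    if mode == "UDO":
        return base, base, base / fold
    if mode == "other":
        # strictly intermediate yet significantly off parents and midparent
        p, m = (base * fold**2, base) if high_first else (base, base * fold**2)
        return p, m, base * fold
    if mode == "absent_in_P":
        return 0.0, base, base
    if mode == "absent_in_M":
        return base, 0.0, base
    if mode == "absent_in_both_parents":
        return 0.0, 0.0, base
    raise ValueError(f"unknown mode {mode!r}")


def _balance_columns(levels: np.ndarray) -> np.ndarray:
    """Per-gene trio multipliers making each nonzero column sum to 1e6.

    Every mode relation is homogeneous of degree 1 in a gene's (P, M, F1)
    trio, so scaling a whole trio preserves it. We solve for the least-norm
    multiplier vector t around 1 with sum(t * col) = 1e6 for each column that
    is not identically zero.
    """
    cols = [j for j in range(3) if levels[:, j].sum() > 0]
    if not cols:
        return levels
    a = levels[:, cols].astype(float)
    nonzero = a > 0
    # Sinkhorn-style preconditioning: repeatedly scale each trio by the
    # geometric mean of its nonzero columns' required factors
    for _ in range(200):
        factors = 1e6 / a.sum(axis=0)
        if np.allclose(factors, 1.0, rtol=1e-12):
            break
        logf = np.log(factors)
        t = np.exp((nonzero * logf).sum(axis=1) / nonzero.sum(axis=1))
        a *= t[:, None]
    # least-norm correction around 1, damped to keep all multipliers positive.
    # Exact balance is structurally infeasible for mixtures with hybrid-only
    # expression (absent-in-both-parents genes always push the F1 column above
    # the parents' average); the damped step then gets as close as positivity
    # allows, which sampling renormalization makes statistically irrelevant.
    target = np.full(len(cols), 1e6)
    gram = a.T @ a
    w = np.linalg.pinv(gram) @ (target - a.sum(axis=0))
    step = a @ w
    alpha = 1.0
    if step.min() < -0.9:
        alpha = 0.9 / -step.min()
    t = 1.0 + alpha * step
    out = np.zeros_like(levels)
    out[:, cols] = a * t[:, None]
    return out


def assign_gene_action_profiles(
    genes: Sequence[SyntheticGene],
    mode_proportions: Mapping[str, float] | None = None,
    tpm_range: tuple[float, float] = (20.0, 2000.0),
    fold_effect: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign a gene-action mode and true TPM trio to every gene.

    Returns the simulation truth table: one row per gene with columns
    ``gene_id, mode, tpm_P, tpm_M, tpm_F1, detectable``. Parents that are
    "different" differ by ``fold_effect`` (>= 2 guarantees |log2 ratio| >= 1).
    Every per-gene mode invariant (e.g. additive F1 = (P+M)/2) holds exactly;
    genotype columns are rescaled to sum to 1e6 via per-gene trio multipliers
    (exact for mixtures without absent_* modes; hybrid-only expression makes
    an exactly balanced F1 column infeasible, so those mixtures come as close
    as positive multipliers allow).
    """
    props = dict(DEFAULT_MODE_PROPORTIONS if mode_proportions is None else mode_proportions)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode proportions sum to {total}, expected 1")
    unknown = set(props) - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes: {sorted(unknown)}")
    if fold_effect < 2:
        raise ValueError("fold_effect must be >= 2")
    lo, hi = tpm_range
    if not (0 < lo <= hi):
        raise ValueError(f"impossible tpm_range {tpm_range}")

    rng = np.random.default_rng(seed)
    names = list(props)
    modes = rng.choice(names, size=len(genes), p=[props[k] for k in names])
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    high_first = rng.random(len(genes)) < 0.5

    levels = np.array(
        [
            _mode_levels(m, b, h, fold_effect)
            for m, b, h in zip(modes, base, high_first)
        ]
    )
    levels = _balance_columns(levels)

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "mode": modes,
            "tpm_P": levels[:, 0],
            "tpm_M": levels[:, 1],
            "tpm_F1": levels[:, 2],
            "detectable": [g.detectable for g in genes],
        }
    )
    return truth


def sample_counts(
    truth: pd.DataFrame,
    genotype: str,
    depth: int = 4_200_000,
    seed: int = 0,
) -> pd.Series:
    """Multinomial tag-count draw for one library, at the given depth.

    Only detectable genes (a canonical tag exists) with positive true TPM can
    emit tags; their TPMs are renormalized to a sampling distribution.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    tpm = truth[f"tpm_{genotype}"].to_numpy(dtype=float)
    mask = truth["detectable"].to_numpy(dtype=bool) & (tpm > 0)
    counts = np.zeros(len(truth), dtype=np.int64)
    if mask.any():
        p = tpm[mask] / tpm[mask].sum()
        counts[mask] = rng.multinomial(depth, p)
    return pd.Series(counts, index=truth["gene_id"].to_numpy(), name=genotype)


def _encode_tags(tags: Iterable[str]) -> np.ndarray:
    joined = "".join(tags)
    return np.frombuffer(joined.encode(), dtype=np.uint8).reshape(-1, TAG_LEN)


def simulate_library(
    truth: pd.DataFrame,
    genes: Sequence[SyntheticGene],
    genotype: str,
    depth: int = 4_200_000,
    error_rate: float = 0.01,
    antisense_fraction: float = 0.05,
    seed: int = 0,
    adaptor: str = DEFAULT_ADAPTOR,
) -> tuple[list[str], pd.Series]:
    """Simulate one raw 35-bp read library for a genotype.

    Each read is a 21-nt canonical tag plus 14 nt of 3' adaptor. A
    Bernoulli(antisense_fraction) draw replaces the sense tag with the gene's
    antisense-strand tag (the read as sequenced from the reverse complement);
    genes without an antisense CATG site fall back to the sense tag. Each
    base is then substituted independently with probability ``error_rate``.
    Returns the reads (shuffled order) and the per-gene true sampled counts.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    if not 0 <= antisense_fraction <= 1:
        raise ValueError("antisense_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = sample_counts(truth, genotype, depth=depth, seed=int(rng.integers(2**31)))

    by_id = {g.gene_id: g for g in genes}
    emitting = counts[counts > 0]
    n_reads = int(emitting.sum())
    if n_reads == 0:
        return [], counts

    sense = _encode_tags(by_id[g].canonical_tag for g in emitting.index)
    anti = _encode_tags(
        (by_id[g].antisense_tag or by_id[g].canonical_tag) for g in emitting.index
    )
    gene_idx = np.repeat(np.arange(len(emitting)), emitting.to_numpy())

    use_anti = rng.random(n_reads) < antisense_fraction
    tags = np.where(use_anti[:, None], anti[gene_idx], sense[gene_idx])

    adaptor_fill = np.frombuffer(
        adaptor[: READ_LEN - TAG_LEN].encode(), dtype=np.uint8
    )
    reads = np.concatenate(
        [tags, np.broadcast_to(adaptor_fill, (n_reads, READ_LEN - TAG_LEN))], axis=1
    )

    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        if err.any():
            code = np.zeros(256, dtype=np.uint8)
            code[_BASES] = np.arange(4)
            shifted = (code[reads[err]] + rng.integers(1, 4, size=int(err.sum()))) % 4
            reads[err] = _BASES[shifted]

    order = rng.permutation(n_reads)
    reads = reads[order]
    buf = reads.tobytes()
    read_list = [
        buf[i * READ_LEN : (i + 1) * READ_LEN].decode() for i in range(n_reads)
    ]
    return read_list, counts
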