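"""Mode-of-gene-action classification for an inbred-parent/F1 trio.

A gene differentially expressed somewhere in the trio is classified by three
contrasts — F1 vs P, F1 vs M, and F1 vs the midparent value MPV = (P+M)/2 —
into: additivity (F1 indistinguishable from the midparent), high-/low-parent
dominance (F1 matches the higher/lower parent and differs from the other),
over-/under-dominance (F1 significantly above/below both parents), or other
(e.g. strictly intermediate between distinguishable parents).

The midparent contrast is realized as a pseudo-library: a library of size
N_MP = round((N_P + N_M)/2) with count round((x_P/N_P + x_M/N_M)/2 * N_MP),
tested against the F1 count with the same exact test as the pairwise
contrasts. Additivity is judged on statistical significance of this contrast
(FDR threshold); a fold-change threshold is configurable but defaults to 0
because a dominant gene's F1/midparent ratio 2f/(f+1) is below 2 for every
parental fold f, so any fold cut-off >= 1 on the midparent contrast would
leave dominance undetectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import (
    DEFAULT_FDR,
    DEFAULT_LFC,
    DEFAULT_PSEUDO_TAGS,
    DifferentialCall,
    bh_adjust,
    call_differential,
    exact_count_test,
    log2_ratio,
)

CATEGORIES = ("additivity", "HPD", "LPD", "ODO", "UDO", "other")

#: Display names used in pattern strings (P is the B73-like paternal line,
#: M the Mo17-like maternal line).
PARENT_NAMES = {"P": "B73", "M": "Mo17"}

DEFAULT_MIDPARENT_LFC = 0.0


@dataclass
class GeneActionCall:
    gene_id: str
    category: str
    pattern: str
    f1_vs_p: DifferentialCall
    f1_vs_m: DifferentialCall
    f1_vs_mp: DifferentialCall


def midparent_counts(p_count, m_count, n_p: int, n_m: int) -> tuple:
    """Pseudo-library size and count for the midparent expression level."""
    n_mp = int(round((n_p + n_m) / 2))
    count = np.round(
        (np.asarray(p_count) / n_p + np.asarray(m_count) / n_m) / 2.0 * n_mp
    ).astype(np.int64)
    return count, n_mp


def midparent_contrast(
    f1_count: int,
    p_count: int,
    m_count: int,
    n_f1: int,
    n_p: int,
    n_m: int,
    gene_id: str = "",
    fdr: float | None = None,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_MIDPARENT_LFC,
    pseudo_tags: float = DEFAULT_PSEUDO_TAGS,
) -> DifferentialCall:
    """F1-vs-midparent call for one gene.

    ``fdr`` may be supplied when BH correction was applied over all genes of
    the contrast; without it, the raw p-value stands in (single-gene use).
    """
    if f1_count == 0 and p_count == 0 and m_count == 0:
        raise ValueError("all-zero gene must be excluded before calling")
    count_mp, n_mp = midparent_counts(p_count, m_count, n_p, n_m)
    count_mp = int(count_mp)
    p_value = exact_count_test(count_mp, f1_count, n_mp, n_f1)
    tpm_mp = count_mp / n_mp * 1e6
    tpm_f1 = f1_count / n_f1 * 1e6
    l2r = log2_ratio(tpm_mp, tpm_f1, n_mp, n_f1, pseudo_tags)
    q = p_value if fdr is None else fdr
    significant = q <= fdr_threshold and abs(l2r) >= lfc_threshold
    return DifferentialCall(
        gene_id=gene_id,
        contrast="F1-vs-MP",
        x=count_mp,
        y=f1_count,
        n1=n_mp,
        n2=n_f1,
        tpm_x=tpm_mp,
        tpm_y=tpm_f1,
        log2_ratio=l2r,
        p_value=p_value,
        fdr=q,
        significant=significant,
        direction="up" if (significant and l2r > 0) else ("down" if significant else "none"),
    )


def _pattern(
    f1vp: DifferentialCall, f1vm: DifferentialCall, parents_differ: bool | None
) -> str:
    """Human-readable ordering string such as 'Mo17 < F1 ≈ B73'.

    The relation of F1 to each parent comes from the pairwise calls; the
    relation between the parents is '<' when ``parents_differ`` (from the
    P-vs-M call if available, else unequal parental TPM), otherwise '≈'.
    """
    p_name, m_name = PARENT_NAMES["P"], PARENT_NAMES["M"]
    rel_f1 = {
        p_name: "≈" if not f1vp.significant else f1vp.direction,
        m_name: "≈" if not f1vm.significant else f1vm.direction,
    }
    (lo_tpm, lo_name), (hi_tpm, hi_name) = sorted(
        [(f1vp.tpm_x, p_name), (f1vm.tpm_x, m_name)]
    )
    if parents_differ is None:
        parents_differ = lo_tpm != hi_tpm

    # F1 sits between the parents unless strictly outside their range
    f1_tpm = f1vp.tpm_y
    if f1_tpm < lo_tpm:
        order = ["F1", lo_name, hi_name]
    elif f1_tpm > hi_tpm:
        order = [lo_name, hi_name, "F1"]
    else:
        order = [lo_name, "F1", hi_name]

    parts = [order[0]]
    for prev, name in zip(order, order[1:]):
        pair = {prev, name}
        if pair == {p_name, m_name}:
            sep = " < " if parents_differ else " ≈ "
        else:
            parent = (pair - {"F1"}).pop()
            sep = " ≈ " if rel_f1[parent] == "≈" else " < "
        parts.append(sep + name)
    return "".join(parts)


def classify_gene_action(
    f1vp: DifferentialCall,
    f1vm: DifferentialCall,
    f1vmp: DifferentialCall,
    parents_differ: bool | None = None,
) -> GeneActionCall:
    """Classify one gene's mode of gene action from its three contrasts.

    Decision order: (1) F1 vs midparent not significant -> additivity;
    (2) F1 significantly above both parents -> ODO; (3) below both -> UDO;
    (4) significant versus exactly one parent -> HPD when the parent F1
    matches is the higher-expressed one (by parental TPM), LPD when it is the
    lower; parental TPM ties with one significant contrast -> other;
    (5) anything else (e.g. strictly intermediate) -> other.
    """
    gid = f1vp.gene_id
    if not (gid == f1vm.gene_id == f1vmp.gene_id):
        raise ValueError("contrast calls must refer to the same gene")
    if not (
        f1vp.contrast == "F1-vs-P"
        and f1vm.contrast == "F1-vs-M"
        and f1vmp.contrast == "F1-vs-MP"
    ):
        raise ValueError("contrast labels inconsistent with (F1-vs-P, F1-vs-M, F1-vs-MP)")

    sig_p, sig_m = f1vp.significant, f1vm.significant
    if not f1vmp.significant:
        category = "additivity"
    elif sig_p and sig_m and f1vp.direction == "up" and f1vm.direction == "up":
        category = "ODO"
    elif sig_p and sig_m and f1vp.direction == "down" and f1vm.direction == "down":
        category = "UDO"
    elif sig_p != sig_m:
        tpm_p, tpm_m = f1vp.tpm_x, f1vm.tpm_x
        if tpm_p == tpm_m:
            category = "other"
        else:
            matched_parent_tpm = tpm_m if sig_p else tpm_p
            category = "HPD" if matched_parent_tpm == max(tpm_p, tpm_m) else "LPD"
    else:
        category = "other"
    return GeneActionCall(
        gene_id=gid,
        category=category,
        pattern=_pattern(f1vp, f1vm, parents_differ),
        f1_vs_p=f1vp,
        f1_vs_m=f1vm,
        f1_vs_mp=f1vmp,
    )


def classify_trio(
    table,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    midparent_lfc_threshold: float = DEFAULT_MIDPARENT_LFC,
    pseudo_tags: float = DEFAULT_PSEUDO_TAGS,
    pairwise_calls: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Classify every gene of the differential universe of a trio table.

    The universe is the set of genes significant in at least one pairwise
    contrast (F1-vs-P, F1-vs-M, P-vs-M). The midparent contrast is computed
    for universe genes with BH correction across that universe. Returns one
    row per universe gene with the category, pattern, and the statistics of
    all three F1 contrasts.
    """
    if pairwise_calls is None:
        pairwise_calls = {
            c: call_differential(table, c, fdr_threshold, lfc_threshold, pseudo_tags)
            for c in ("F1-vs-P", "F1-vs-M", "P-vs-M")
        }
    universe: set[str] = set()
    for calls in pairwise_calls.values():
        universe |= set(calls.loc[calls["significant"], "gene_id"])
    universe_idx = sorted(universe)
    if not universe_idx:
        return pd.DataFrame(
            columns=["gene_id", "category", "pattern"]
        )

    n_p = table.clean_totals["P"]
    n_m = table.clean_totals["M"]
    n_f1 = table.clean_totals["F1"]
    sub = table.counts.loc[universe_idx]
    mp_count, n_mp = midparent_counts(sub["P"].to_numpy(), sub["M"].to_numpy(), n_p, n_m)
    f1 = sub["F1"].to_numpy()
    p_mp = exact_count_test(mp_count, f1, n_mp, n_f1)
    fdr_mp = bh_adjust(p_mp)

    by_gene = {
        c: df.set_index("gene_id") for c, df in pairwise_calls.items()
    }
    pvm = by_gene["P-vs-M"]

    rows = []
    for i, gid in enumerate(universe_idx):
        f1vp = _lookup_call(by_gene["F1-vs-P"], gid, table, "P", fdr_threshold, lfc_threshold)
        f1vm = _lookup_call(by_gene["F1-vs-M"], gid, table, "M", fdr_threshold, lfc_threshold)
        f1vmp = midparent_contrast(
            int(f1[i]),
            int(sub["P"].iloc[i]),
            int(sub["M"].iloc[i]),
            n_f1,
            n_p,
            n_m,
            gene_id=gid,
            fdr=float(fdr_mp[i]),
            fdr_threshold=fdr_threshold,
            lfc_threshold=midparent_lfc_threshold,
            pseudo_tags=pseudo_tags,
        )
        parents_differ = bool(pvm.loc[gid, "significant"]) if gid in pvm.index else None
        call = classify_gene_action(f1vp, f1vm, f1vmp, parents_differ=parents_differ)
        rows.append(
            {
                "gene_id": gid,
                "category": call.category,
                "pattern": call.pattern,
                "count_P": int(sub["P"].iloc[i]),
                "count_M": int(sub["M"].iloc[i]),
                "count_F1": int(f1[i]),
                "log2_f1_vs_p": f1vp.log2_ratio,
                "fdr_f1_vs_p": f1vp.fdr,
                "log2_f1_vs_m": f1vm.log2_ratio,
                "fdr_f1_vs_m": f1vm.fdr,
                "log2_f1_vs_mp": f1vmp.log2_ratio,
                "fdr_f1_vs_mp": f1vmp.fdr,
            }
        )
    return pd.DataFrame(rows)


def _lookup_call(calls_df, gid, table, parent, fdr_threshold, lfc_threshold):
    """Fetch a pairwise F1 call; synthesize a non-significant call when the
    gene was untested in that contrast (zero counts in both libraries)."""
    contrast = f"F1-vs-{parent}"
    if gid in calls_df.index:
        row = calls_df.loc[gid]
        return DifferentialCall(
            gene_id=gid,
            contrast=contrast,
            x=int(row["x"]),
            y=int(row["y"]),
            n1=int(row["n1"]),
            n2=int(row["n2"]),
            tpm_x=float(row["tpm_x"]),
            tpm_y=float(row["tpm_y"]),
            log2_ratio=float(row["log2_ratio"]),
            p_value=float(row["p_value"]),
            fdr=float(row["fdr"]),
            significant=bool(row["significant"]),
            direction=str(row["direction"]),
        )
    n1 = table.clean_totals[parent]
    n2 = table.clean_totals["F1"]
    return DifferentialCall(
        gene_id=gid,
        contrast=contrast,
        x=0,
        y=0,
        n1=n1,
        n2=n2,
        tpm_x=0.0,
        tpm_y=0.0,
        log2_ratio=0.0,
        p_value=1.0,
        fdr=1.0,
        significant=False,
        direction="none",
    )


def summarize_gene_action(calls: pd.DataFrame) -> dict[str, int]:
    """Category counts in the shape of the study's gene-action summary table.

    ``non_additivity`` is the sum of HPD, LPD, ODO, UDO and other; ``total``
    is additivity plus non-additivity. Holds on any input by construction.
    """
    counts = {c: 0 for c in CATEGORIES}
    if len(calls):
        vc = calls["category"].value_counts()
        for c in CATEGORIES:
            counts[c] = int(vc.get(c, 0))
    non_add = sum(counts[c] for c in CATEGORIES if c != "additivity")
    return {
        "total": counts["additivity"] + non_add,
        "additivity": counts["additivity"],
        "non_additivity": non_add,
        "HPD": counts["HPD"],
        "LPD": counts["LPD"],
        "ODO": counts["ODO"],
        "UDO": counts["UDO"],
        "other": counts["other"],
    }


def gene_action_percentages(summary: dict[str, int], ndigits: int = 1) -> dict[str, float]:
    """Percentages of the differential universe per category.

    Accepts the output of summarize_gene_action (or an equivalent mapping of
    printed counts) and derives the shares the reporting table prints.
    """
    total = summary["total"]
    if total <= 0:
        return {f"pct_{k}": 0.0 for k in summary if k != "total"}
    return {
        f"pct_{k}": round(100.0 * v / total, ndigits)
        for k, v in summary.items()
        if k != "total"
    }
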