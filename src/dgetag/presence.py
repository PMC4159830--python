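"""Presence/absence expression patterns across the trio, and PAV reports.

A gene is "present" in a library when it has at least ``min_count``
unambiguous sense tags (default 1 — the assay has no stated detection floor,
so a single unambiguous tag counts as detection). The three presence booleans
partition genes into eight classes; the study's summary table covers the six
cells with at least one parent absent crossed with hybrid presence.
"""

from __future__ import annotations

import pandas as pd

#: Presence classes as functions of (present_P, present_M, present_F1).
_CLASS = {
    (True, True, True): "present_in_all",
    (True, True, False): "present_in_both_parents_other",
    (True, False, True): "P_only_hybrid_present",
    (True, False, False): "P_only_hybrid_absent",
    (False, True, True): "M_only_hybrid_present",
    (False, True, False): "M_only_hybrid_absent",
    (False, False, True): "parents_absent_hybrid_present",
    (False, False, False): "absent_in_all",
}

#: The six summary cells: (row: hybrid present/absent) x (column).
TABLE_COLUMNS = ("P_only", "M_only", "absent_both_parents")


def classify_presence(table, min_count: int = 1) -> pd.DataFrame:
    """Per-gene presence booleans and class for a P/M/F1 expression table."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    present = table.counts >= min_count
    cls = [
        _CLASS[(bool(p), bool(m), bool(f))]
        for p, m, f in zip(present["P"], present["M"], present["F1"])
    ]
    return pd.DataFrame(
        {
            "gene_id": table.counts.index,
            "present_P": present["P"].to_numpy(),
            "present_M": present["M"].to_numpy(),
            "present_F1": present["F1"].to_numpy(),
            "class": cls,
        }
    ).set_index("gene_id")


def presence_summary_from_counts(
    p_only_hybrid_present: int,
    p_only_hybrid_absent: int,
    m_only_hybrid_present: int,
    m_only_hybrid_absent: int,
    parents_absent_hybrid_present: int,
    parents_absent_hybrid_absent: int = 0,
    n_expressed: int | None = None,
    ndigits: int = 1,
) -> dict:
    """Summary-table arithmetic from the six cell counts.

    Produces column totals, each column's percentage of the summary universe,
    the hybrid present:absent ratio per parent-specific column, the grand
    total, and (when ``n_expressed`` is given) the universe's percentage of
    all expressed genes.
    """
    grid = pd.DataFrame(
        [
            [p_only_hybrid_present, m_only_hybrid_present, parents_absent_hybrid_present],
            [p_only_hybrid_absent, m_only_hybrid_absent, parents_absent_hybrid_absent],
        ],
        index=["hybrid_present", "hybrid_absent"],
        columns=list(TABLE_COLUMNS),
    )
    col_totals = grid.sum(axis=0)
    total = int(col_totals.sum())
    out = {
        "grid": grid,
        "column_totals": col_totals.to_dict(),
        "total": total,
    }
    for col in TABLE_COLUMNS:
        out[f"pct_{col}"] = round(100.0 * col_totals[col] / total, ndigits) if total else 0.0
    for col in ("P_only", "M_only"):
        absent = grid.loc["hybrid_absent", col]
        out[f"hybrid_ratio_{col}"] = (
            round(grid.loc["hybrid_present", col] / absent, 2) if absent else None
        )
    if n_expressed:
        out["pct_of_expressed"] = round(100.0 * total / n_expressed, ndigits)
    return out


def presence_summary(
    presence: pd.DataFrame, n_expressed: int | None = None
) -> dict:
    """Summary of the presence classes of a trio (study summary-table shape).

    The universe is every gene absent in at least one parent but detected
    somewhere in the trio.
    """
    vc = presence["class"].value_counts()
    get = lambda k: int(vc.get(k, 0))
    return presence_summary_from_counts(
        get("P_only_hybrid_present"),
        get("P_only_hybrid_absent"),
        get("M_only_hybrid_present"),
        get("M_only_hybrid_absent"),
        get("parents_absent_hybrid_present"),
        0,
        n_expressed=n_expressed,
    )


def pav_crossref(
    presence: pd.DataFrame,
    table,
    pav_list: pd.DataFrame,
    gene_action_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-reference a presence/absence-variation gene list with the assay.

    ``pav_list`` has columns ``gene_id`` and ``present_in_genome`` (P or M,
    the donor genome carrying the gene). Per PAV gene the report gives: a
    resolvable flag (the id exists in the reference), a detected-by-tags
    flag, the presence pattern, the relation of F1 expression to the parents
    (equal-to-one-parent / above both / below both / between), whether the
    gene shows the single-parent-plus-hybrid complementation pattern, and the
    gene-action category when the gene is in the differential universe.
    """
    required = {"gene_id", "present_in_genome"}
    if not required <= set(pav_list.columns):
        raise ValueError(f"PAV list needs columns {sorted(required)}")
    tpm = table.tpm
    action = (
        gene_action_calls.set_index("gene_id")["category"]
        if gene_action_calls is not None and len(gene_action_calls)
        else pd.Series(dtype=object)
    )
    rows = []
    for _, rec in pav_list.iterrows():
        gid = rec["gene_id"]
        resolvable = gid in presence.index
        if not resolvable:
            rows.append(
                {
                    "gene_id": gid,
                    "present_in_genome": rec["present_in_genome"],
                    "resolvable": False,
                    "detected": False,
                    "class": None,
                    "f1_relation": None,
                    "complementation": False,
                    "category": None,
                }
            )
            continue
        pr = presence.loc[gid]
        detected = bool(pr[["present_P", "present_M", "present_F1"]].any())
        t_p, t_m, t_f1 = (float(tpm.loc[gid, c]) for c in ("P", "M", "F1"))
        if not detected:
            relation = None
        elif t_f1 == t_p or t_f1 == t_m:
            relation = "equal_to_one_parent"
        elif t_f1 > max(t_p, t_m):
            relation = "above_both"
        elif t_f1 < min(t_p, t_m):
            relation = "below_both"
        else:
            relation = "between"
        complementation = bool(
            pr["present_F1"] and (pr["present_P"] != pr["present_M"])
        )
        rows.append(
            {
                "gene_id": gid,
                "present_in_genome": rec["present_in_genome"],
                "resolvable": True,
                "detected": detected,
                "class": pr["class"],
                "f1_relation": relation,
                "complementation": complementation,
                "category": action.get(gid),
            }
        )
    return pd.DataFrame(rows)


def pav_summary_from_counts(
    n_pav: int,
    n_mapped: int,
    n_mapped_p_only: int | None = None,
    ndigits: int = 1,
) -> dict:
    """PAV report arithmetic: the fractions the study prints.

    ``n_mapped`` is the number of PAV genes detected by tags; the optional
    ``n_mapped_p_only`` is how many of those were expressed only in the
    B73-like parent.
    """
    if n_pav < 1:
        raise ValueError("empty PAV list")
    out = {
        "n_pav": n_pav,
        "n_mapped": n_mapped,
        "pct_mapped": round(100.0 * n_mapped / n_pav, ndigits),
    }
    if n_mapped_p_only is not None:
        out["n_mapped_p_only"] = n_mapped_p_only
        out["pct_mapped_p_only"] = (
            round(100.0 * n_mapped_p_only / n_mapped, ndigits) if n_mapped else 0.0
        )
    return out


def pav_summary(report: pd.DataFrame, ndigits: int = 1) -> dict:
    """Fractions over a pav_crossref report (study-style PAV accounting)."""
    mapped = report[report["detected"]]
    p_only = mapped["class"].isin(["P_only_hybrid_present", "P_only_hybrid_absent"])
    out = pav_summary_from_counts(
        len(report), len(mapped), int(p_only.sum()), ndigits=ndigits
    )
    out["n_single_parent_plus_hybrid"] = int(mapped["complementation"].sum())
    out["n_single_parent_hybrid_absent"] = int(
        mapped["class"].isin(["P_only_hybrid_absent", "M_only_hybrid_absent"]).sum()
    )
    out["n_parents_absent_hybrid_present"] = int(
        (mapped["class"] == "parents_absent_hybrid_present").sum()
    )
    return out
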