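"""Read counting, RPKM, and Stekel's R differential-expression statistic.

Stekel's R is the log-likelihood ratio for heterogeneity of a gene's counts
x_j across cDNA libraries of sizes N_j:

    f = sum_j x_j / sum_j N_j
    R = sum_j x_j * ln( x_j / (N_j * f) )        (x_j = 0 terms contribute 0)

R = 0 exactly when the counts are proportional to the library totals; large
R flags library-dependent expression.  Natural logarithms are used.  A gene
is eligible when every compared library holds at least ``min_reads`` reads
(default 5) and differential when additionally R >= 7.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "count_reads",
    "rpkm",
    "stekel_r",
    "call_differential",
    "compare_homeolog_pairs",
]


def count_reads(membership: dict, libraries: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Per-contig per-library read counts.

    ``membership`` maps read id -> contig id; ``libraries`` maps library
    name -> iterable of read ids.  Totals are the mapped reads per library.
    A read id duplicated within a library raises.
    """
    lib_names = list(libraries)
    contigs = sorted(set(membership.values()))
    counts = pd.DataFrame(0, index=contigs, columns=lib_names, dtype=int)
    totals = {}
    for lib in lib_names:
        seen = set()
        mapped = 0
        for rid in libraries[lib]:
            if rid in seen:
                raise ValueError(f"duplicate read id {rid!r} in library {lib!r}")
            seen.add(rid)
            contig = membership.get(rid)
            if contig is not None:
                counts.loc[contig, lib] += 1
                mapped += 1
        totals[lib] = mapped
    return counts, pd.Series(totals)


def rpkm(count: float, contig_len: int, library_total: int) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if contig_len <= 0:
        raise ValueError("contig_len must be > 0")
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    return 1e9 * count / (contig_len * library_total)


def stekel_r(counts, totals) -> float:
    """Stekel's log-likelihood ratio R for one gene across libraries."""
    x = np.asarray(counts, dtype=float)
    N = np.asarray(totals, dtype=float)
    if x.shape != N.shape or x.size < 2:
        raise ValueError("need counts and totals for >= 2 libraries")
    if (N <= 0).any():
        raise ValueError("library totals must be > 0")
    if (x < 0).any():
        raise ValueError("counts must be >= 0")
    total_x = x.sum()
    if total_x == 0:
        return 0.0
    f = total_x / N.sum()
    nz = x > 0
    r = float(np.sum(x[nz] * np.log(x[nz] / (N[nz] * f))))
    return max(r, 0.0)


def call_differential(
    counts: pd.DataFrame,
    totals: pd.Series,
    min_reads: int = 5,
    r_cutoff: float = 7.0,
) -> pd.DataFrame:
    """Eligibility, R, differential flag, and trend per row of ``counts``.

    Eligible rows have >= ``min_reads`` in every library; differential rows
    are eligible with R >= ``r_cutoff``.  The trend names the library with
    the largest rate deviation and its direction.
    """
    totals = totals[counts.columns]
    out = []
    for contig, row in counts.iterrows():
        x = row.to_numpy(dtype=float)
        r = stekel_r(x, totals.to_numpy(dtype=float))
        eligible = bool((x >= min_reads).all())
        differential = bool(eligible and r >= r_cutoff)
        trend = ""
        if differential:
            rates = x / totals.to_numpy(dtype=float)
            expected = x.sum() / totals.sum()
            dev = rates / expected
            k = int(np.argmax(np.abs(np.log(np.where(dev > 0, dev, 1e-300)))))
            trend = f"{counts.columns[k]}_{'up' if dev[k] > 1 else 'down'}"
        out.append(
            {
                "contig": contig,
                "r_stat": r,
                "eligible": eligible,
                "differential": differential,
                "trend": trend,
            }
        )
    return pd.DataFrame(out).set_index("contig")


def compare_homeolog_pairs(
    pairs,
    counts: pd.DataFrame,
    lengths: dict,
    totals: pd.Series,
    polyploid_lib: str,
    parent_libs: tuple = ("parent_s", "parent_t"),
    min_reads: int = 5,
    r_cutoff: float = 7.0,
) -> tuple[pd.DataFrame, dict]:
    """Homeolog-pair expression comparison for dual-copy (AB_AC) clusters.

    ``pairs`` is an iterable of dicts with keys ``cluster``, ``s_contig``,
    ``t_contig``, ``parent_s_contig``, ``parent_t_contig``.  For each
    cluster the S- and T-copy RPKM within the polyploid and the parental
    homolog RPKM pair are reported, with a per-pair Stekel R (S vs T counts
    in the polyploid library) and differential flag.  Pairs where either
    polyploid copy has fewer than ``min_reads`` reads are ineligible.

    Returns the per-pair table and summary statistics including Pearson
    correlations (on RPKM and on log10 RPKM) over eligible pairs.
    """
    rows = []
    for pair in pairs:
        cs, ct = pair["s_contig"], pair["t_contig"]
        ps, pt = pair["parent_s_contig"], pair["parent_t_contig"]
        x_s = float(counts.loc[cs, polyploid_lib])
        x_t = float(counts.loc[ct, polyploid_lib])
        r = stekel_r(
            [x_s, x_t], [totals[polyploid_lib], totals[polyploid_lib]]
        )
        eligible = x_s >= min_reads and x_t >= min_reads
        rows.append(
            {
                "cluster": pair["cluster"],
                "s_contig": cs,
                "t_contig": ct,
                "reads_s": x_s,
                "reads_t": x_t,
                "rpkm_poly_s": rpkm(x_s, lengths[cs], totals[polyploid_lib]),
                "rpkm_poly_t": rpkm(x_t, lengths[ct], totals[polyploid_lib]),
                "rpkm_parent_s": rpkm(
                    float(counts.loc[ps, parent_libs[0]]),
                    lengths[ps],
                    totals[parent_libs[0]],
                ),
                "rpkm_parent_t": rpkm(
                    float(counts.loc[pt, parent_libs[1]]),
                    lengths[pt],
                    totals[parent_libs[1]],
                ),
                "r_stat": r,
                "eligible": eligible,
                "differential": bool(eligible and r >= r_cutoff),
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {"n_pairs": len(table), "n_eligible": 0}
    if len(table):
        el = table[table["eligible"]]
        summary["n_eligible"] = int(len(el))
        summary["n_differential"] = int(el["differential"].sum())
        if len(el) >= 3:
            for tag, (a, b) in {
                "homeolog": ("rpkm_poly_s", "rpkm_poly_t"),
                "parent": ("rpkm_parent_s", "rpkm_parent_t"),
            }.items():
                x, y = el[a].to_numpy(), el[b].to_numpy()
                r_lin = stats.pearsonr(x, y).statistic
                ok = (x > 0) & (y > 0)
                r_log = (
                    stats.pearsonr(np.log10(x[ok]), np.log10(y[ok])).statistic
                    if ok.sum() >= 3
                    else np.nan
                )
                summary[f"pearson_r_{tag}"] = float(r_lin)
                summary[f"pearson_r2_{tag}"] = float(r_lin**2)
                summary[f"pearson_r_log_{tag}"] = float(r_log)
    return table, summary
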