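"""Score winsorization and the CpG-unit QC cascade.

Maps a raw percent-methylation matrix to the analysis-ready unit set in a
fixed order: missingness filter -> zero-inflation filter -> within-gene
perfect-duplicate collapse -> within-gene correlated-region grouping.
Accounting (units in = removed + retained) is asserted on every run.

Winsorization applies to the questionnaire totals (CTQ, BDI-II) only;
methylation extremes are handled by the [0, 100] value-domain bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    AllUnitsRemovedError,
    AnalysisConfig,
    Cohort,
    CpGUnit,
    InsufficientDataError,
    MethylationMatrix,
)

__all__ = [
    "winsorize_scores",
    "qc_filter_units",
    "collapse_perfect_duplicates",
    "group_regions",
    "RegionGrouping",
    "PreprocessResult",
    "preprocess_cohort",
]

#: Minimum pairwise-complete observations for a correlation to be defined.
_MIN_PAIR_OBS = 3


# ---------------------------------------------------------------------------
# Winsorization
# ---------------------------------------------------------------------------


def winsorize_scores(
    values, k: float = 3.0, mode: str = "largest_within"
) -> tuple[np.ndarray, int]:
    """Cap scores outside mean +- k*SD; returns (adjusted, n_modified).

    Moments are computed on the input values (missing ignored).  In the
    default ``"largest_within"`` mode a high outlier is replaced by the
    largest input value <= mean + k*SD (and symmetrically below); the
    ``"bound"`` mode replaces it with mean + k*SD itself.  Order and
    missingness pattern are preserved.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if mode not in ("largest_within", "bound"):
        raise ValueError(f"unknown winsorization mode {mode!r}")
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 3:
        raise InsufficientDataError(
            f"winsorization needs >= 3 non-missing values, got {finite.size}"
        )
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if sd == 0:
        if np.unique(finite).size > 1:  # unreachable, kept for clarity
            warnings.warn("zero SD with distinct values; winsorization skipped")
        return arr.copy(), 0
    hi_bound = mean + k * sd
    lo_bound = mean - k * sd
    out = arr.copy()
    hi_mask = out > hi_bound
    lo_mask = out < lo_bound
    if mode == "largest_within":
        in_hi = finite[finite <= hi_bound]
        in_lo = finite[finite >= lo_bound]
        hi_repl = float(in_hi.max()) if in_hi.size else hi_bound
        lo_repl = float(in_lo.min()) if in_lo.size else lo_bound
    else:
        hi_repl, lo_repl = hi_bound, lo_bound
    out[hi_mask] = hi_repl
    out[lo_mask] = lo_repl
    return out, int(hi_mask.sum() + lo_mask.sum())


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def qc_filter_units(
    matrix: MethylationMatrix,
    missing_frac_max: float = 0.20,
    zero_frac_min: float = 0.80,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Drop units with excess missingness, then zero-inflated units.

    Returns the filtered matrix and a removal report with columns
    ``unit_id``, ``reason`` ("missingness" | "zero-inflated") and
    ``statistic`` (the offending fraction).  Filters are applied in that
    order; the zero filter evaluates the zero fraction among *non-missing*
    values of missingness survivors.
    """
    vals = matrix.values
    n = len(vals)
    report_rows: list[dict] = []
    missing_frac = vals.isna().sum(axis=0) / n
    drop_missing = missing_frac[missing_frac > missing_frac_max]
    for uid, frac in drop_missing.items():
        report_rows.append({"unit_id": uid, "reason": "missingness", "statistic": float(frac)})
    survivors = [u for u in matrix.unit_ids if u not in set(drop_missing.index)]

    kept: list[str] = []
    for uid in survivors:
        col = vals[uid].dropna()
        zero_frac = float((col == 0).mean()) if len(col) else 1.0
        if zero_frac > zero_frac_min:
            report_rows.append({"unit_id": uid, "reason": "zero-inflated", "statistic": zero_frac})
        else:
            kept.append(uid)
    if not kept:
        raise AllUnitsRemovedError("all units removed by QC filters")
    report = pd.DataFrame(report_rows, columns=["unit_id", "reason", "statistic"])
    return matrix.subset(kept), report


# ---------------------------------------------------------------------------
# Perfect-duplicate collapse
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _pairwise_r(col_a: pd.Series, col_b: pd.Series) -> float | None:
    """Pearson r on pairwise-complete observations; None if < 3 pairs or a
    constant column makes it undefined."""
    ok = col_a.notna() & col_b.notna()
    if ok.sum() < _MIN_PAIR_OBS:
        return None
    a = col_a[ok].to_numpy()
    b = col_b[ok].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def collapse_perfect_duplicates(
    matrix: MethylationMatrix, r_tol: float = 1e-9
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Merge same-gene units that are positively and perfectly correlated.

    Pairs with Pearson r >= 1 - ``r_tol`` on pairwise-complete observations
    are merged transitively (connected components).  The merged unit's values
    are the per-participant available-case mean of its members, its positions
    the sorted union, and its ID the "+"-joined member IDs.  Cross-gene pairs
    are never merged.  Returns (collapsed matrix, merge report).
    """
    vals = matrix.values
    uf = _UnionFind(matrix.unit_ids)
    skipped: list[tuple[str, str]] = []
    by_gene: dict[str, list[CpGUnit]] = {}
    for u in matrix.units:
        by_gene.setdefault(u.gene, []).append(u)
    for gene, units in by_gene.items():
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                a, b = units[i].unit_id, units[j].unit_id
                r = _pairwise_r(vals[a], vals[b])
                if r is None:
                    skipped.append((a, b))
                    continue
                if r >= 1 - r_tol:
                    uf.union(a, b)
    if skipped:
        warnings.warn(
            f"correlation undefined for {len(skipped)} unit pair(s); pairs skipped"
        )

    components: dict[str, list[str]] = {}
    for uid in matrix.unit_ids:
        components.setdefault(uf.find(uid), []).append(uid)

    new_units: list[CpGUnit] = []
    new_cols: dict[str, pd.Series] = {}
    report_rows: list[dict] = []
    for members in components.values():
        members = [u for u in matrix.unit_ids if u in set(members)]  # input order
        if len(members) == 1:
            u = matrix.unit(members[0])
            new_units.append(u)
            new_cols[u.unit_id] = vals[u.unit_id]
            continue
        first = matrix.unit(members[0])
        merged_id = "+".join(sorted(members))
        positions = tuple(sorted({p for m in members for p in matrix.unit(m).positions}))
        merged = CpGUnit(merged_id, first.gene, first.chrom, positions)
        new_units.append(merged)
        new_cols[merged_id] = vals[members].mean(axis=1)  # available-case mean
        report_rows.append(
            {
                "unit_id": merged_id,
                "members": ";".join(members),
                "statistic": min(
                    r
                    for r in (
                        _pairwise_r(vals[a], vals[b])
                        for k, a in enumerate(members)
                        for b in members[k + 1 :]
                    )
                    if r is not None
                ),
            }
        )
    # preserve input ordering by first member position in the original list
    order = {uid: k for k, uid in enumerate(matrix.unit_ids)}
    new_units.sort(key=lambda u: min(order[m] for m in u.unit_id.split("+")))
    out_vals = pd.DataFrame({u.unit_id: new_cols[u.unit_id] for u in new_units})
    report = pd.DataFrame(report_rows, columns=["unit_id", "members", "statistic"])
    if len(report):
        report = report.sort_values("unit_id", ignore_index=True)
    return MethylationMatrix(out_vals, new_units), report


# ---------------------------------------------------------------------------
# Region grouping
# ---------------------------------------------------------------------------


@dataclass
class RegionGrouping:
    """Unit-level matrix plus the derived region-level matrix.

    ``regions`` holds only multi-unit regions (region value = per-participant
    available-case mean of members); singleton units simply remain in the
    unit-level matrix.  ``membership`` maps region_id -> member unit IDs.
    """

    units: MethylationMatrix
    regions: MethylationMatrix
    membership: dict[str, list[str]] = field(default_factory=dict)

    @property
    def report(self) -> pd.DataFrame:
        rows = [
            {"region_id": rid, "members": ";".join(m), "n_units": len(m)}
            for rid, m in sorted(self.membership.items())
        ]
        return pd.DataFrame(rows, columns=["region_id", "members", "n_units"])


def group_regions(
    matrix: MethylationMatrix, r_min: float = 0.50, window_bp: int = 500
) -> RegionGrouping:
    """Chain same-gene units into regions by proximity and correlation.

    Within each gene, units are sorted by first coordinate; two adjacent
    units join the same region when the gap between their nearest
    coordinates is <= ``window_bp`` AND their pairwise r >= ``r_min``.
    Regions are maximal chains under this rule.  Pairs whose correlation is
    undefined (fewer than 3 complete pairs, or a constant column) never join.
    """
    vals = matrix.values
    by_gene: dict[str, list[CpGUnit]] = {}
    for u in matrix.units:
        by_gene.setdefault(u.gene, []).append(u)

    membership: dict[str, list[str]] = {}
    region_units: list[CpGUnit] = []
    region_cols: dict[str, pd.Series] = {}
    n_skipped = 0
    for gene, units in sorted(by_gene.items()):
        units = sorted(units, key=lambda u: (u.chrom, u.start))
        chains: list[list[CpGUnit]] = [[units[0]]] if units else []
        for prev, cur in zip(units, units[1:]):
            gap = cur.start - prev.end  # nearest coordinates of adjacent sorted units
            r = _pairwise_r(vals[prev.unit_id], vals[cur.unit_id])
            if r is None:
                n_skipped += 1
            if prev.chrom == cur.chrom and gap <= window_bp and r is not None and r >= r_min:
                chains[-1].append(cur)
            else:
                chains.append([cur])
        for chain in chains:
            if len(chain) < 2:
                continue
            rid = f"{gene}_region_{chain[0].start}_{chain[-1].end}"
            members = [u.unit_id for u in chain]
            membership[rid] = members
            positions = tuple(sorted({p for u in chain for p in u.positions}))
            region_units.append(CpGUnit(rid, gene, chain[0].chrom, positions))
            region_cols[rid] = vals[members].mean(axis=1)
    if n_skipped:
        warnings.warn(
            f"correlation undefined for {n_skipped} adjacent unit pair(s); not chained"
        )
    regions = MethylationMatrix(
        pd.DataFrame(region_cols, index=vals.index, columns=[u.unit_id for u in region_units]),
        region_units,
    )
    return RegionGrouping(units=matrix, regions=regions, membership=membership)


# ---------------------------------------------------------------------------
# Full preprocessing pass
# ---------------------------------------------------------------------------


@dataclass
class PreprocessResult:
    """Analysis-ready cohort plus the audit trail of every preprocessing step."""

    cohort: Cohort                 # winsorized scores, QC-filtered + collapsed units
    grouping: RegionGrouping
    qc_report: pd.DataFrame
    merge_report: pd.DataFrame
    n_winsorized: dict[str, int]
    accounting: dict[str, int]


def preprocess_cohort(cohort: Cohort, config: AnalysisConfig | None = None) -> PreprocessResult:
    """Winsorize questionnaire totals, run the unit QC cascade, group regions.

    Asserts the filter accounting: units_in = removed + merged-away + retained.
    """
    cfg = config or cohort.config
    ph = cohort.phenotypes.copy()
    n_winsorized: dict[str, int] = {}
    for col in ("maltreatment", "depression"):
        adj, n_mod = winsorize_scores(ph[col].to_numpy(dtype=float), k=cfg.winsor_k)
        ph[col] = adj
        n_winsorized[col] = n_mod

    n_in = len(cohort.methylation.unit_ids)
    filtered, qc_report = qc_filter_units(
        cohort.methylation, cfg.missing_frac_max, cfg.zero_frac_min
    )
    collapsed, merge_report = collapse_perfect_duplicates(filtered, cfg.duplicate_r_tol)
    grouping = group_regions(collapsed, cfg.region_r_min, cfg.region_window_bp)

    n_removed = len(qc_report)
    n_merged_away = sum(
        len(m.split(";")) - 1 for m in merge_report.get("members", pd.Series(dtype=str))
    )
    n_retained = len(collapsed.unit_ids)
    accounting = {
        "units_in": n_in,
        "removed_qc": n_removed,
        "merged_away": n_merged_away,
        "units_analyzed": n_retained,
        "regions": len(grouping.membership),
    }
    assert n_in == n_removed + n_merged_away + n_retained, accounting

    out_cohort = Cohort(ph, collapsed, cfg, dict(cohort.meta))
    return PreprocessResult(
        cohort=out_cohort,
        grouping=grouping,
        qc_report=qc_report,
        merge_report=merge_report,
        n_winsorized=n_winsorized,
        accounting=accounting,
    )
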