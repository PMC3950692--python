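"""Chromatin-mark correlation structure and expression reports.

``mark_correlation`` computes pairwise Spearman correlations of promoter
mark-count profiles across MIRs; the dendrogram leaf order is computed once
from the all-MIRs matrix (average linkage on 1 - rho) and reused for the
intergenic/intragenic submatrices so heatmaps stay comparable.
``mantel_test`` compares two such matrices by the Pearson correlation of
their vectorized upper triangles with a joint label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .mir_models import ModelAssignment
from .promoters import _PointIndex
from .types import ExpressionRecord, GeneRecord, MirRecord, Peak, PromoterCall


@dataclass
class CorrelationMatrix:
    """Square symmetric Spearman matrix with a fixed dendrogram leaf order."""

    matrix: pd.DataFrame
    leaf_order: list[str]

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.columns)

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.leaf_order, self.leaf_order]


def _cluster_order(corr: pd.DataFrame) -> list[str]:
    labels = sorted(corr.columns)  # deterministic tie-break: smaller label first
    corr = corr.loc[labels, labels]
    dist = 1.0 - corr.to_numpy()
    dist = np.where(np.isfinite(dist), dist, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    if len(labels) < 3:
        return labels
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return [labels[i] for i in hierarchy.leaves_list(linkage)]


def mark_correlation(
    profile: pd.DataFrame,
    subset: str = "all",
    context_map: Mapping[str, str] | None = None,
    leaf_order: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise Spearman correlation of mark columns over MIR rows.

    ``subset`` restricts rows to "intergenic" or "intragenic" MIRs using
    ``context_map``; the leaf order should then be passed in from the
    all-MIRs run. Constant columns yield NaN correlations (not-applicable).
    """
    if subset != "all":
        if context_map is None:
            raise ValueError("context_map required for a context subset")
        rows = [m for m in profile.index if context_map.get(m) == subset]
        profile = profile.loc[rows]
    if len(profile) < 3 or profile.shape[1] < 2:
        raise ValueError("need >= 3 MIR rows and >= 2 mark columns")
    corr = profile.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    order = list(leaf_order) if leaf_order is not None else _cluster_order(corr)
    return CorrelationMatrix(corr, order)


def mantel_test(
    m1: CorrelationMatrix | pd.DataFrame,
    m2: CorrelationMatrix | pd.DataFrame,
    n_permutations: int,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two labelled square matrices.

    Returns (r, p): r is the Pearson correlation of the upper triangles and
    p the add-one permutation p-value obtained by jointly permuting the
    rows/columns of the second matrix.
    """
    a = m1.matrix if isinstance(m1, CorrelationMatrix) else m1
    b = m2.matrix if isinstance(m2, CorrelationMatrix) else m2
    if list(a.columns) != list(b.columns):
        b = b.loc[a.columns, a.columns]
    n = a.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs matrices of size >= 3")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    iu = np.triu_indices(n, k=1)
    x_full = a.to_numpy()[iu]
    y_mat = b.to_numpy()

    def corr(y):
        # not-applicable (NaN) entries from constant columns are masked out
        mask = np.isfinite(x_full) & np.isfinite(y)
        if mask.sum() < 3:
            return np.nan
        return np.corrcoef(x_full[mask], y[mask])[0, 1]

    r_obs = float(corr(y_mat[iu]))
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(y_mat[np.ix_(perm, perm)][iu]) >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# RNAPII intensity vs expression

def _promoter_intensity(
    chrom: str | None,
    tss: int | None,
    index: _PointIndex,
    window: int,
) -> float:
    if chrom is None or tss is None:
        return 0.0
    pos = index._pos.get(chrom)
    if pos is None or pos.size == 0:
        return 0.0
    i0 = int(np.searchsorted(pos, tss - window, side="left"))
    i1 = int(np.searchsorted(pos, tss + window, side="right"))
    return float(index._intensity[chrom][i0:i1].sum())


def intensity_expression_report(
    promoter_calls: Sequence[PromoterCall],
    rnapii_peaks: Sequence[Peak],
    expression: Sequence[ExpressionRecord],
    mirs: Sequence[MirRecord],
    genes: Sequence[GeneRecord],
    config: PipelineConfig,
) -> dict:
    """RNAPII promoter intensity versus expression, per cell line.

    Promoter intensity is the sum of peak intensities whose centers fall
    within +/- ``anchor_tss_window`` of the TSS. Reports (a) MIR intensity
    vs MIR RPM (Spearman + quartile bins), (b) intragenic MIR intensity vs
    host FPKM (Pearson), (c) MIR vs nearest-gene promoter intensity
    stratified by relative strand (nearest gene TSS within
    ``neighbor_max_gap``). Strata with < 3 usable pairs are not-applicable.
    """
    by_mir = {m.mir_id: m for m in mirs}
    gene_by_id = {g.gene_id: g for g in genes}
    calls = [c for c in promoter_calls if c.tss is not None]
    expr = pd.DataFrame(
        [(r.entity_id, r.cell_line, r.value) for r in expression],
        columns=["entity_id", "cell_line", "value"],
    )
    w = config.anchor_tss_window

    gene_tss_sorted: dict[str, tuple[np.ndarray, list[GeneRecord]]] = {}
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.tss)
        gene_tss_sorted[chrom] = (
            np.array([g.tss for g in glist], dtype=np.int64),
            glist,
        )

    report: dict[str, dict] = {}
    for cell, sub in expr.groupby("cell_line"):
        values = dict(zip(sub["entity_id"], sub["value"]))
        pol = _PointIndex([p for p in rnapii_peaks if p.cell_line == cell])
        intensity = {
            c.mir_id: _promoter_intensity(c.chrom, c.tss, pol, w) for c in calls
        }

        # (a) MIR promoter intensity vs MIR expression
        pairs = [
            (intensity[c.mir_id], values[c.mir_id])
            for c in calls
            if c.mir_id in values
        ]
        section_a = _spearman_with_quartiles(pairs)

        # (b) intragenic MIRs: intensity vs host expression
        xy = [
            (intensity[c.mir_id], values[by_mir[c.mir_id].host_gene_id])
            for c in calls
            if c.mir_id in by_mir
            and by_mir[c.mir_id].context == "intragenic"
            and by_mir[c.mir_id].host_gene_id in values
        ]
        if len(xy) >= 3 and np.ptp([p[0] for p in xy]) > 0 and np.ptp(
            [p[1] for p in xy]
        ) > 0:
            r, p = sps.pearsonr([p[0] for p in xy], [p[1] for p in xy])
            section_b = {"pearson_r": float(r), "p": float(p), "n": len(xy)}
        else:
            section_b = {"pearson_r": None, "p": None, "n": len(xy)}

        # (c) MIR vs nearest-gene promoter intensity by relative strand
        strata: dict[str, list[tuple[float, float]]] = {"same": [], "opposite": []}
        for c in calls:
            mir = by_mir.get(c.mir_id)
            if mir is None or c.chrom not in gene_tss_sorted:
                continue
            pos_arr, glist = gene_tss_sorted[c.chrom]
            i = int(np.searchsorted(pos_arr, c.tss))
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(glist):
                    d = abs(int(pos_arr[j]) - c.tss)
                    if best is None or d < best[0]:
                        best = (d, glist[j])
            if best is None or best[0] > config.neighbor_max_gap:
                continue
            gene = best[1]
            key = (
                "same"
                if gene.interval.strand == mir.pre_mirna.strand
                else "opposite"
            )
            strata[key].append(
                (
                    intensity[c.mir_id],
                    _promoter_intensity(gene.interval.chrom, gene.tss, pol, w),
                )
            )
        section_c = {}
        for key, xy2 in strata.items():
            if len(xy2) >= 3 and np.ptp([p[0] for p in xy2]) > 0 and np.ptp(
                [p[1] for p in xy2]
            ) > 0:
                r, p = sps.pearsonr([p[0] for p in xy2], [p[1] for p in xy2])
                section_c[key] = {"pearson_r": float(r), "p": float(p), "n": len(xy2)}
            else:
                section_c[key] = {"pearson_r": None, "p": None, "n": len(xy2)}

        report[cell] = {
            "intensity_vs_expression": section_a,
            "intragenic_vs_host": section_b,
            "nearby_gene_by_strand": section_c,
        }
    return report


def _spearman_with_quartiles(pairs: list[tuple[float, float]]) -> dict:
    if len(pairs) < 3:
        return {"spearman_rho": None, "p": None, "n": len(pairs), "quartile_means": None}
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"spearman_rho": None, "p": None, "n": len(pairs), "quartile_means": None}
    rho, p = sps.spearmanr(x, y)
    qlabels = pd.qcut(pd.Series(x).rank(method="first"), 4, labels=False)
    qmeans = [float(y[qlabels == q].mean()) for q in range(4)]
    return {
        "spearman_rho": float(rho),
        "p": float(p),
        "n": len(pairs),
        "quartile_means": qmeans,
    }


# ---------------------------------------------------------------------------
# expression by chromatin model

MODEL_GROUPS = ("interaction/mir_mir", "interaction/mir_gene_only", "basal", "not_assigned")


def expression_by_model(
    assignments: Sequence[ModelAssignment],
    expression: Sequence[ExpressionRecord],
    cell_line: str,
) -> pd.DataFrame:
    """Pairwise one-sided Mann-Whitney contrasts of expression across models.

    Groups follow the expected activity ordering mir_mir >= mir_gene_only >=
    basal >= not_assigned; each row tests 'earlier group greater'. Pairs
    with an empty group are skipped.
    """
    values = {
        r.entity_id: r.value for r in expression if r.cell_line == cell_line
    }
    groups: dict[str, list[float]] = {g: [] for g in MODEL_GROUPS}
    for a in assignments:
        key = a.model if a.submodel is None else f"{a.model}/{a.submodel}"
        if key in groups and a.mir_id in values:
            groups[key].append(values[a.mir_id])
    populated = [g for g in MODEL_GROUPS if groups[g]]
    if len(populated) < 2:
        raise ValueError("need >= 2 populated model groups")
    rows = []
    for i, g1 in enumerate(populated):
        for g2 in populated[i + 1:]:
            u, p = sps.mannwhitneyu(groups[g1], groups[g2], alternative="greater")
            rows.append(
                {
                    "group_high": g1,
                    "group_low": g2,
                    "n_high": len(groups[g1]),
                    "n_low": len(groups[g2]),
                    "median_high": float(np.median(groups[g1])),
                    "median_low": float(np.median(groups[g2])),
                    "U": float(u),
                    "p": float(p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group_high", "group_low", "n_high", "n_low",
            "median_high", "median_low", "U", "p",
        ],
    )
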