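"""Tiered TSS assignment and promoter classification for MIRs.

TSS evidence is combined in a fixed precedence cascade: a curated TSS beats
CAGE tag evidence, which beats RNAPII peak evidence. For the CAGE and RNAPII
tiers the candidate must lie in the strand-aware upstream window (0 to
``tss_search_window`` bases from the pre-miRNA 5' end, both ends inclusive)
and the nearest candidate wins; distance ties break to the higher intensity,
then to the smaller coordinate. An RNAPII-tier TSS is the peak center.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .types import GeneRecord, MirRecord, Peak, PromoterCall


def _curated_map(curated) -> dict[str, tuple[str, int]]:
    if curated is None:
        return {}
    if isinstance(curated, pd.DataFrame):
        return {
            str(r.mir_id): (str(r.chrom), int(r.tss)) for r in curated.itertuples()
        }
    return {k: (str(c), int(t)) for k, (c, t) in dict(curated).items()}


class _PointIndex:
    """Per-chromosome sorted point candidates (position, intensity)."""

    def __init__(self, peaks: Iterable[Peak]):
        bychrom: dict[str, list[tuple[int, float]]] = defaultdict(list)
        for p in peaks:
            bychrom[p.interval.chrom].append((p.center, p.intensity))
        self._pos: dict[str, np.ndarray] = {}
        self._intensity: dict[str, np.ndarray] = {}
        for chrom, items in bychrom.items():
            items.sort()
            self._pos[chrom] = np.array([i[0] for i in items], dtype=np.int64)
            self._intensity[chrom] = np.array([i[1] for i in items], dtype=float)

    def nearest_upstream(
        self, chrom: str, five_prime: int, strand: str, window: int
    ) -> int | None:
        """Best candidate position in the upstream window, or None.

        Upstream of a '+' feature is [five_prime - window, five_prime]; of a
        '-' feature [five_prime, five_prime + window]; both inclusive.
        """
        pos = self._pos.get(chrom)
        if pos is None or pos.size == 0:
            return None
        if strand == "+":
            lo, hi = five_prime - window, five_prime
        elif strand == "-":
            lo, hi = five_prime, five_prime + window
        else:
            raise ValueError("upstream is undefined without a strand")
        i0 = int(np.searchsorted(pos, lo, side="left"))
        i1 = int(np.searchsorted(pos, hi, side="right"))
        if i0 >= i1:
            return None
        cand = pos[i0:i1]
        inten = self._intensity[chrom][i0:i1]
        dist = np.abs(cand - five_prime)
        # nearest; ties -> higher intensity, then smaller coordinate
        order = np.lexsort((cand, -inten, dist))
        return int(cand[order[0]])


def assign_tss(
    mirs: Sequence[MirRecord],
    curated_tss,
    cage_tags: Iterable[Peak],
    rnapii_peaks: Iterable[Peak],
    config: PipelineConfig,
) -> list[PromoterCall]:
    """Assign a TSS to each MIR by the three-tier evidence cascade."""
    curated = _curated_map(curated_tss)
    cage_index = _PointIndex(cage_tags or [])
    pol_index = _PointIndex(rnapii_peaks or [])
    calls = []
    for mir in mirs:
        chrom = mir.pre_mirna.chrom
        strand = mir.pre_mirna.strand
        if mir.mir_id in curated:
            c_chrom, c_tss = curated[mir.mir_id]
            calls.append(
                PromoterCall(mir.mir_id, c_tss, c_chrom, "curated")
            )
            continue
        tss = cage_index.nearest_upstream(
            chrom, mir.five_prime_end, strand, config.tss_search_window
        )
        if tss is not None:
            calls.append(PromoterCall(mir.mir_id, tss, chrom, "cage"))
            continue
        tss = pol_index.nearest_upstream(
            chrom, mir.five_prime_end, strand, config.tss_search_window
        )
        if tss is not None:
            calls.append(PromoterCall(mir.mir_id, tss, chrom, "rnapii"))
            continue
        calls.append(PromoterCall(mir.mir_id, None, None, "none"))
    return calls


def classify_promoter_sharing(
    calls: Sequence[PromoterCall],
    genes: Sequence[GeneRecord],
    config: PipelineConfig,
) -> list[PromoterCall]:
    """Mark each promoter-bearing call shared vs isolated.

    A promoter is shared when at least one protein-coding gene TSS lies
    within +/- ``promoter_share_window`` (inclusive) of the MIR TSS,
    regardless of strand.
    """
    bychrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for g in genes:
        bychrom[g.interval.chrom].append((g.tss, g.gene_id))
    pos: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    for chrom, items in bychrom.items():
        items.sort()
        pos[chrom] = np.array([i[0] for i in items], dtype=np.int64)
        ids[chrom] = [i[1] for i in items]

    out = []
    w = config.promoter_share_window
    for call in calls:
        if call.tss is None:
            out.append(call)
            continue
        shared: frozenset[str] = frozenset()
        p = pos.get(call.chrom)
        if p is not None and p.size:
            i0 = int(np.searchsorted(p, call.tss - w, side="left"))
            i1 = int(np.searchsorted(p, call.tss + w, side="right"))
            shared = frozenset(ids[call.chrom][i0:i1])
        out.append(
            replace(
                call,
                promoter_class="shared" if shared else "isolated",
                shared_gene_ids=shared,
            )
        )
    return out


def annotate_h3k4me3_support(
    calls: Sequence[PromoterCall],
    h3k4me3_peaks: Iterable[Peak],
    config: PipelineConfig,
) -> list[PromoterCall]:
    """Flag calls with >= 1 H3K4me3 peak center in the promoter-share window.

    This reported flag replaces manual promoter verification; it is not used
    as a filter anywhere downstream.
    """
    index = _PointIndex(h3k4me3_peaks)
    w = config.promoter_share_window
    out = []
    for call in calls:
        if call.tss is None:
            out.append(call)
            continue
        pos = index._pos.get(call.chrom)
        supported = False
        if pos is not None and pos.size:
            i0 = np.searchsorted(pos, call.tss - w, side="left")
            i1 = np.searchsorted(pos, call.tss + w, side="right")
            supported = i1 > i0
        out.append(replace(call, h3k4me3_supported=bool(supported)))
    return out


def mark_profile(
    calls: Sequence[PromoterCall],
    peaks: Iterable[Peak],
    config: PipelineConfig,
    marks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count peak centers within +/- ``mark_profile_window`` of each TSS.

    Returns a DataFrame indexed by mir_id (promoter-bearing calls only) with
    one integer column per mark; replicates of a mark are pooled by
    summation. Requesting a mark absent from the peak set is an error.
    """
    peaks = list(peaks)
    available = sorted({p.mark for p in peaks})
    if marks is None:
        marks = available
    else:
        unknown = set(marks) - set(available)
        if unknown:
            raise ValueError(f"unknown mark(s) requested: {sorted(unknown)}")
    indexes = {
        m: _PointIndex([p for p in peaks if p.mark == m]) for m in marks
    }
    w = config.mark_profile_window
    rows = {}
    for call in calls:
        if call.tss is None:
            continue
        counts = []
        for m in marks:
            pos = indexes[m]._pos.get(call.chrom)
            if pos is None or pos.size == 0:
                counts.append(0)
                continue
            i0 = np.searchsorted(pos, call.tss - w, side="left")
            i1 = np.searchsorted(pos, call.tss + w, side="right")
            counts.append(int(i1 - i0))
        rows[call.mir_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(marks))
    df.index.name = "mir_id"
    return df


def promoter_calls_frame(calls: Sequence[PromoterCall]) -> pd.DataFrame:
    """Tabular view of promoter calls (for promoter_calls.tsv)."""
    return pd.DataFrame(
        [
            {
                "mir_id": c.mir_id,
                "chrom": c.chrom if c.chrom is not None else ".",
                "tss": c.tss if c.tss is not None else -1,
                "evidence_tier": c.evidence_tier,
                "promoter_class": c.promoter_class,
                "shared_gene_ids": ",".join(sorted(c.shared_gene_ids)) or ".",
                "h3k4me3_supported": int(c.h3k4me3_supported),
            }
            for c in calls
        ]
    )


def calls_from_frame(df: pd.DataFrame) -> list[PromoterCall]:
    calls = []
    for r in df.itertuples():
        tss = None if int(r.tss) < 0 else int(r.tss)
        shared = frozenset(
            s for s in str(r.shared_gene_ids).split(",") if s and s != "."
        )
        calls.append(
            PromoterCall(
                str(r.mir_id),
                tss,
                None if str(r.chrom) == "." else str(r.chrom),
                str(r.evidence_tier),
                str(r.promoter_class),
                shared,
                bool(int(r.h3k4me3_supported)),
            )
        )
    return calls


def tier_counts(calls: Sequence[PromoterCall]) -> Mapping[str, int]:
    out = {"curated": 0, "cage": 0, "rnapii": 0, "none": 0}
    for c in calls:
        out[c.evidence_tier] += 1
    return out
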