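"""Readers and writers for the file formats the pipeline touches.

Dialects
--------
* GFF3: 1-based inclusive on disk, converted to 0-based half-open in memory.
* BED / BEDPE: 0-based half-open, headerless, ``#`` comment lines allowed.
  Peak BED is BED3+ with optional columns name, score (-> intensity), strand
  and summit offset (column 7, relative to start).
  Interaction BEDPE carries three extra columns: pet_count, cell_line,
  replicate_id.
* TSV tables: tab-separated, ``#`` comments, header row required.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    DuplexInteraction,
    ExpressionRecord,
    GeneRecord,
    GenomicInterval,
    MirRecord,
    Peak,
    TargetPair,
    make_duplex,
)

_GFF_EXTS = {".gff", ".gff3"}


def _is_gff(path: Path) -> bool:
    return path.suffix.lower() in _GFF_EXTS


def read_table(path: str | Path) -> pd.DataFrame:
    """TSV with a header row and '#' comment lines."""
    return pd.read_csv(
        path, sep="\t", comment="#", dtype={"chrom": str},
        float_precision="round_trip",
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations

def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _gff_rows(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            yield lineno, fields, start, end


def read_annotations(path: str | Path, kind: str) -> list[GeneRecord] | list[MirRecord]:
    """Load gene or MIR annotations from GFF3 or TSV.

    ``kind`` is "gene" or "mir". TSV coordinates are already 0-based
    half-open; GFF3 is converted on read. Malformed lines raise with the
    offending line number.
    """
    path = Path(path)
    if kind not in ("gene", "mir"):
        raise ValueError("kind must be 'gene' or 'mir'")
    if _is_gff(path):
        records = []
        for lineno, fields, start, end in _gff_rows(path):
            attrs = _parse_gff_attributes(fields[8])
            iv = GenomicInterval(fields[0], start - 1, end, fields[6])
            try:
                if kind == "gene":
                    records.append(
                        GeneRecord(attrs["ID"], attrs.get("Name", attrs["ID"]), iv)
                    )
                else:
                    records.append(_mir_from_attrs(attrs["ID"], iv, attrs))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return records
    df = read_table(path)
    if kind == "gene":
        return [
            GeneRecord(
                str(r.gene_id),
                str(r.symbol),
                GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            )
            for r in df.itertuples()
        ]
    return [
        _mir_from_attrs(
            str(r.mir_id),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            {
                "context": str(r.context),
                "host_gene": _na(r.host_gene_id),
                "cluster": _na(r.cluster_id),
                "family": _na(r.family_id),
                "diseases": _na(r.disease_categories) or "",
            },
        )
        for r in df.itertuples()
    ]


def _na(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    value = str(value)
    return None if value in ("", ".", "nan") else value


def _mir_from_attrs(mir_id: str, iv: GenomicInterval, attrs: dict) -> MirRecord:
    diseases = frozenset(
        d for d in (attrs.get("diseases") or "").split(",") if d
    )
    return MirRecord(
        mir_id=mir_id,
        pre_mirna=iv,
        context=attrs.get("context", "intergenic"),
        host_gene_id=_na(attrs.get("host_gene")),
        cluster_id=_na(attrs.get("cluster")),
        family_id=_na(attrs.get("family")),
        disease_categories=diseases,
    )


def write_annotations(records: Sequence[GeneRecord | MirRecord], path: str | Path) -> None:
    """Write annotations as GFF3 (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            if isinstance(rec, GeneRecord):
                iv, ftype = rec.interval, "gene"
                attrs = f"ID={rec.gene_id};Name={rec.symbol}"
            else:
                iv, ftype = rec.pre_mirna, "pre_miRNA"
                parts = [f"ID={rec.mir_id}", f"context={rec.context}"]
                if rec.host_gene_id:
                    parts.append(f"host_gene={rec.host_gene_id}")
                if rec.cluster_id:
                    parts.append(f"cluster={rec.cluster_id}")
                if rec.family_id:
                    parts.append(f"family={rec.family_id}")
                if rec.disease_categories:
                    parts.append("diseases=" + ",".join(sorted(rec.disease_categories)))
                attrs = ";".join(parts)
            fh.write(
                f"{iv.chrom}\t.\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def check_mir_hosts(mirs: Iterable[MirRecord], genes: Iterable[GeneRecord]) -> None:
    """Validate that intragenic MIRs cite a known host and lie within it."""
    by_id = {g.gene_id: g for g in genes}
    for mir in mirs:
        if mir.context != "intragenic":
            continue
        host = by_id.get(mir.host_gene_id)
        if host is None:
            raise ValueError(f"{mir.mir_id}: unresolvable host {mir.host_gene_id}")
        hi, pi = host.interval, mir.pre_mirna
        inside = hi.chrom == pi.chrom and hi.start <= pi.start and pi.end <= hi.end
        if not inside or hi.strand != pi.strand:
            raise ValueError(
                f"{mir.mir_id}: intragenic MIR must lie within {host.gene_id} "
                "on the same strand"
            )


# ---------------------------------------------------------------------------
# interactions (BEDPE + pet_count, cell_line, replicate_id)

def read_interactions(path: str | Path) -> list[DuplexInteraction]:
    """Load duplex interactions; duplicates within one replicate are collapsed
    with their PET counts summed."""
    path = Path(path)
    merged: dict[tuple, int] = {}
    order: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 BEDPE columns")
            try:
                dup = make_duplex(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                    int(f[6]),
                    f[7],
                    f[8],
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            key = (
                dup.anchor_a.chrom, dup.anchor_a.start, dup.anchor_a.end,
                dup.anchor_b.chrom, dup.anchor_b.start, dup.anchor_b.end,
                dup.cell_line, dup.replicate_id,
            )
            if key not in merged:
                order.append(key)
                merged[key] = 0
            merged[key] += dup.pet_count
    return [
        DuplexInteraction(
            GenomicInterval(k[0], k[1], k[2]),
            GenomicInterval(k[3], k[4], k[5]),
            merged[k],
            k[6],
            k[7],
        )
        for k in order
    ]


def write_interactions(interactions: Sequence[DuplexInteraction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tpet_count\tcell_line\treplicate_id\n"
        )
        for d in interactions:
            a, b = d.anchor_a, d.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{d.pet_count}\t{d.cell_line}\t{d.replicate_id}\n"
            )


# ---------------------------------------------------------------------------
# peaks

def read_peaks(
    path: str | Path, mark: str, cell_line: str, replicate_id: str
) -> list[Peak]:
    """Load a single-track peak BED file.

    Optional column 5 is the intensity score (missing -> 0) and optional
    column 7 a summit offset relative to start; without a summit the center
    is ``floor((start + end) / 2)``.
    """
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            if score < 0:
                raise ValueError(f"{path}:{lineno}: negative score")
            if len(f) > 6 and f[6] not in (".", ""):
                center = start + int(f[6])
            else:
                center = (start + end) // 2
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    center,
                    score,
                    mark,
                    cell_line,
                    replicate_id,
                )
            )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write a single-track peak BED (name '.', strand '.', summit kept)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{p.intensity:g}\t.\t"
                f"{p.center - iv.start}\n"
            )


def read_peak_table(path: str | Path) -> list[Peak]:
    """Combined peak TSV with mark/cell_line/replicate_id columns."""
    df = read_table(path)
    return [
        Peak(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            int(r.center),
            float(r.intensity),
            str(r.mark),
            str(r.cell_line),
            str(r.replicate_id),
        )
        for r in df.itertuples()
    ]


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "center": p.center,
                "intensity": repr(p.intensity),  # exact float round-trip
                "mark": p.mark,
                "cell_line": p.cell_line,
                "replicate_id": p.replicate_id,
            }
            for p in peaks
        ],
        columns=[
            "chrom", "start", "end", "center", "intensity",
            "mark", "cell_line", "replicate_id",
        ],
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# plain interval BED (blacklist, TADs)

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# simple record tables

def read_expression(path: str | Path) -> list[ExpressionRecord]:
    df = read_table(path)
    return [
        ExpressionRecord(str(r.entity_id), str(r.cell_line), float(r.value))
        for r in df.itertuples()
    ]


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.entity_id, r.cell_line, repr(r.value)) for r in records],
        columns=["entity_id", "cell_line", "value"],
    )
    write_table(df, path)


def read_targets(path: str | Path) -> list[TargetPair]:
    df = read_table(path)
    return [
        TargetPair(str(r.mir_id), str(r.target_gene_id), int(r.n_databases))
        for r in df.itertuples()
    ]


def write_targets(pairs: Sequence[TargetPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.mir_id, p.target_gene_id, p.n_databases) for p in pairs],
        columns=["mir_id", "target_gene_id", "n_databases"],
    )
    write_table(df, path)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
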