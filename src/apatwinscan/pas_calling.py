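"""Poly(A)-site calling: deduplication, single-linkage clustering of read
3'-ends, and reduction to per-gene two-PAS count tables."""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DISTAL,
    PROXIMAL,
    DataError,
    GeneModel,
    PASCluster,
    PASRecord,
    ReadEnd,
    TwoPASTable,
    validate_count_matrix,
)

DEDUP_MODES = ("umi", "position", "none")


def _as_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        df = reads.copy()
        if "umi" not in df.columns:
            df["umi"] = None
        return df[["chrom", "site", "strand", "umi"]]
    return pd.DataFrame(
        [(r.chrom, r.site, r.strand, r.umi) for r in reads],
        columns=["chrom", "site", "strand", "umi"],
    )


def _dedup(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "none":
        return df
    if mode == "position":
        return df.drop_duplicates(subset=["chrom", "strand", "site"])
    if mode == "umi":
        # reads without a UMI are kept as-is
        has = df["umi"].notna()
        kept = df[has].drop_duplicates(subset=["chrom", "strand", "site", "umi"])
        return pd.concat([kept, df[~has]], ignore_index=True)
    raise DataError(f"unknown dedup mode {mode!r}; expected one of {DEDUP_MODES}")


def call_pas_sites(
    reads_by_sample: Mapping[str, "pd.DataFrame | Iterable[ReadEnd]"],
    gap: int = 24,
    dedup: str = "umi",
) -> list[PASCluster]:
    """Cluster deduplicated read 3'-ends into poly(A) sites.

    Single-linkage clustering per (chrom, strand): adjacent distinct
    positions at most *gap* bases apart join the same cluster. The
    representative cleavage site is the modal position over pooled
    per-sample counts; ties go to the 3'-most position (largest coordinate
    on '+', smallest on '-').
    """
    if dedup not in DEDUP_MODES:
        raise DataError(f"unknown dedup mode {dedup!r}; expected one of {DEDUP_MODES}")
    parts = []
    for sample, reads in reads_by_sample.items():
        df = _dedup(_as_frame(reads), dedup)
        df = df.assign(sample=sample)
        parts.append(df)
    if not parts:
        return []
    allreads = pd.concat(parts, ignore_index=True)
    if allreads.empty:
        return []
    counts = (
        allreads.groupby(["chrom", "strand", "site", "sample"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    clusters: list[PASCluster] = []
    for (chrom, strand), grp in counts.groupby(["chrom", "strand"], sort=True):
        pos_tot = grp.groupby("site")["n"].sum().sort_index()
        sites = pos_tot.index.to_numpy()
        breaks = np.where(np.diff(sites) > gap)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(sites)]])
        site_to_cluster = {}
        for k in range(len(bounds) - 1):
            members = sites[bounds[k] : bounds[k + 1]]
            tot = pos_tot.loc[members]
            best = tot.max()
            tied = tot.index[tot == best].to_numpy()
            cleavage = int(tied.max() if strand == "+" else tied.min())
            cl = PASCluster(
                chrom=chrom,
                strand=strand,
                cleavage_site=cleavage,
                positions={int(s): int(tot.loc[s]) for s in members},
                sample_counts={},
            )
            clusters.append(cl)
            for s in members:
                site_to_cluster[int(s)] = cl
        for _, row in grp.iterrows():
            cl = site_to_cluster[int(row["site"])]
            cl.sample_counts[row["sample"]] = (
                cl.sample_counts.get(row["sample"], 0) + int(row["n"])
            )
    return clusters


def quantify_pas_counts(
    clusters: Sequence[PASCluster], samples: Sequence[str]
) -> pd.DataFrame:
    """Cluster x sample matrix of deduplicated read-end counts."""
    known = set()
    for cl in clusters:
        known.update(cl.sample_counts)
    missing = known - set(samples)
    if missing:
        warnings.warn(f"samples {sorted(missing)} absent from requested columns")
    rows = {
        cl.cluster_id: [cl.sample_counts.get(s, 0) for s in samples]
        for cl in sorted(clusters, key=lambda c: (c.chrom, c.cleavage_site, c.strand))
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    df.index.name = "pas_id"
    return validate_count_matrix(df)


def build_two_pas_table(
    clusters: Sequence[PASCluster],
    genes: Sequence[GeneModel],
    min_minor_fraction: float = 0.05,
    min_gene_count: int = 20,
) -> tuple[list[TwoPASTable], dict]:
    """Assign clusters to genes and reduce each gene to its two strongest
    PASs.

    A gene is retained iff its pooled two-PAS count reaches
    *min_gene_count* and the minor PAS holds at least *min_minor_fraction*
    of the two-PAS total. Clusters overlapping multiple genes are
    rejected. Returns (tables, log summary).
    """
    by_locus: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_locus.setdefault((g.chrom, g.strand), []).append(g)

    assigned: dict[str, list[PASCluster]] = {}
    log = {"ambiguous_clusters": 0, "unassigned_clusters": 0,
           "genes_lt2_clusters": 0, "genes_failed_cutoffs": 0}
    for cl in clusters:
        hits = [
            g
            for g in by_locus.get((cl.chrom, cl.strand), [])
            if g.contains(cl.cleavage_site)
        ]
        if len(hits) == 0:
            log["unassigned_clusters"] += 1
        elif len(hits) > 1:
            log["ambiguous_clusters"] += 1
        else:
            assigned.setdefault(hits[0].gene_id, []).append(cl)

    gene_by_id = {g.gene_id: g for g in genes}
    tables: list[TwoPASTable] = []
    for gene_id, cls in assigned.items():
        if len(cls) < 2:
            log["genes_lt2_clusters"] += 1
            continue
        top2 = sorted(cls, key=lambda c: (-c.total_count, c.cleavage_site))[:2]
        tot = top2[0].total_count + top2[1].total_count
        minor = min(c.total_count for c in top2)
        if tot < min_gene_count or (tot > 0 and minor / tot < min_minor_fraction):
            log["genes_failed_cutoffs"] += 1
            continue
        g = gene_by_id[gene_id]
        a, b = sorted(top2, key=lambda c: c.cleavage_site)
        prox, dist = (a, b) if g.strand == "+" else (b, a)
        tables.append(
            TwoPASTable(
                gene_id=gene_id,
                proximal=PASRecord(
                    gene_id, PROXIMAL, g.chrom, g.strand,
                    prox.cleavage_site, dict(prox.sample_counts),
                ),
                distal=PASRecord(
                    gene_id, DISTAL, g.chrom, g.strand,
                    dist.cleavage_site, dict(dist.sample_counts),
                ),
            )
        )
    tables.sort(key=lambda t: t.gene_id)
    return tables, log


def write_pas_bed(tables: Sequence[TwoPASTable], path) -> None:
    """BED6 of called PASs: name = '<gene>|P/D', score = pooled count."""
    with open(path, "w") as fh:
        for t in tables:
            for rec in (t.proximal, t.distal):
                fh.write(
                    f"{rec.chrom}\t{rec.cleavage_site}\t{rec.cleavage_site + 1}\t"
                    f"{rec.pas_id}\t{sum(rec.counts.values())}\t{rec.strand}\n"
                )


def read_pas_bed(path) -> dict[str, tuple[str, int, str]]:
    """Inverse of write_pas_bed: pas_id -> (chrom, cleavage_site, strand)."""
    out: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6 or "|" not in fields[3]:
                raise DataError(f"line {lineno}: not a PAS BED record")
            out[fields[3]] = (fields[0], int(fields[1]), fields[5])
    return out


def tables_from_artifacts(
    counts: pd.DataFrame, pas_sites: Mapping[str, tuple[str, int, str]]
) -> list[TwoPASTable]:
    """Rebuild TwoPASTables from a written count table plus PAS BED."""
    validate_count_matrix(counts)
    tables = []
    genes = sorted({i.rsplit("|", 1)[0] for i in counts.index})
    for g in genes:
        recs = {}
        for label in (PROXIMAL, DISTAL):
            pid = f"{g}|{label}"
            if pid not in pas_sites or pid not in counts.index:
                raise DataError(f"PAS {pid!r} missing from counts or PAS BED")
            chrom, site, strand = pas_sites[pid]
            recs[label] = PASRecord(
                g, label, chrom, strand, site, counts.loc[pid].to_dict()
            )
        tables.append(TwoPASTable(g, recs[PROXIMAL], recs[DISTAL]))
    return tables


def two_pas_count_matrix(
    tables: Sequence[TwoPASTable], samples: Sequence[str]
) -> pd.DataFrame:
    """Stack per-gene two-PAS counts into a '<gene>|P/D' x sample matrix."""
    frames = [t.counts_frame(samples) for t in tables]
    if not frames:
        return pd.DataFrame(columns=list(samples))
    df = pd.concat(frames)
    df.index.name = "pas_id"
    return validate_count_matrix(df)
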