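"""Readers and writers for the standard formats the pipeline touches.

Supported formats: BED6 read 3'-ends, BED12 / GTF gene models, FASTA
genomes, TSV count and design tables. Sequences are uppercased and U is
normalized to T on input; all coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .datamodel import (
    DataError,
    GeneModel,
    ReadEnd,
    SampleDesign,
    validate_count_matrix,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# gene annotation


def _gene_from_bed12(fields: list[str], lineno: int) -> GeneModel:
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise DataError(f"malformed BED12 record at line {lineno}: {exc}") from exc
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise DataError(f"line {lineno}: block count does not match block lists")
    exons = tuple(
        (chrom_start + bs, chrom_start + bs + sz)
        for bs, sz in zip(block_starts, block_sizes)
    )
    if thick_start == thick_end:
        cds_end = None
    else:
        cds_end = thick_end - 1 if strand == "+" else thick_start
    return GeneModel(
        gene_id=name, chrom=chrom, strand=strand, exons=exons, cds_end=cds_end
    )


def _read_bed12(path: PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise DataError(
                    f"malformed BED12 record at line {lineno}: "
                    f"expected 12 fields, got {len(fields)}"
                )
            if fields[5] not in ("+", "-"):
                warnings.warn(
                    f"line {lineno}: missing/invalid strand, record rejected"
                )
                continue
            genes.append(_gene_from_bed12(fields, lineno))
    return genes


def _read_gtf(path: PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    seen: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            warnings.warn(f"feature for {gid}: missing strand, record rejected")
            continue
        rec = seen.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        iv = (feat.start - 1, feat.end)  # GFF is 1-based inclusive
        (rec["exons"] if feat.featuretype == "exon" else rec["cds"]).append(iv)
    for gid, rec in seen.items():
        cds_end = None
        if rec["cds"]:
            cds_end = (
                max(e for _, e in rec["cds"]) - 1
                if rec["strand"] == "+"
                else min(s for s, _ in rec["cds"])
            )
        exons = rec["exons"] or rec["cds"]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(exons),
                cds_end=cds_end,
            )
        )
    return genes


def read_gene_annotation(path: PathLike) -> list[GeneModel]:
    """Read gene models from a BED12 (``.bed``) or GTF/GFF file."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _read_gtf(path)
    return _read_bed12(path)


def write_gene_annotation(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.span
            if g.cds_end is None:
                thick_s = thick_e = start
            elif g.strand == "+":
                thick_s, thick_e = start, g.cds_end + 1
            else:
                thick_s, thick_e = g.cds_end, end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            start,
                            end,
                            g.gene_id,
                            0,
                            g.strand,
                            thick_s,
                            thick_e,
                            0,
                            len(g.exons),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# read 3'-ends (BED6)


def read_read_ends(path: PathLike, as_frame: bool = False):
    """Read aligned read 3'-ends from BED6.

    The 3' end is the ``end-1`` coordinate for '+' records and the
    ``start`` coordinate for '-' records. The name field is taken as a UMI
    when it is not ".".
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(
                    f"line {lineno}: BED6 requires 6 fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataError(
                    f"line {lineno}: non-numeric coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if start >= end:
                warnings.warn(f"line {lineno}: start >= end, record rejected")
                continue
            if strand not in ("+", "-"):
                warnings.warn(f"line {lineno}: invalid strand, record rejected")
                continue
            site = end - 1 if strand == "+" else start
            umi = None if name == "." else name
            rows.append((chrom, site, strand, umi))
    frame = pd.DataFrame(rows, columns=["chrom", "site", "strand", "umi"])
    if as_frame:
        return frame
    return [ReadEnd(*row) for row in rows]


def write_read_ends(
    reads, path: PathLike, read_length: int = 25
) -> None:
    """Write read ends as BED6, reconstructing a nominal read interval."""
    if isinstance(reads, pd.DataFrame):
        it = reads.itertuples(index=False)
        rows = [(r.chrom, r.site, r.strand, r.umi) for r in it]
    else:
        rows = [(r.chrom, r.site, r.strand, r.umi) for r in reads]
    with open(path, "w") as fh:
        for chrom, site, strand, umi in rows:
            if strand == "+":
                start, end = max(0, site - read_length + 1), site + 1
            else:
                start, end = site, site + read_length
            name = umi if umi else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA into a dict; sequences uppercased with U normalized to T."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DataError(f"duplicate FASTA header {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# count / design tables


def read_count_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "pas_id"
    try:
        df = df.astype("int64")
    except ValueError as exc:
        raise DataError(f"non-integer count in {path}: {exc}") from exc
    return validate_count_matrix(df)


def write_count_table(counts: pd.DataFrame, path: PathLike) -> None:
    validate_count_matrix(counts)
    counts.to_csv(path, sep="\t", index_label="pas_id")


def read_design(path: PathLike) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "batch", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"design table missing columns: {sorted(missing)}")
    return [
        SampleDesign(
            sample_id=row["sample"],
            condition=row["condition"],
            batch=row["batch"],
            library_size=int(row["library_size"]),
        )
        for _, row in df.iterrows()
    ]


def write_design(design: Sequence[SampleDesign], path: PathLike) -> None:
    pd.DataFrame(
        {
            "sample": [d.sample_id for d in design],
            "condition": [d.condition for d in design],
            "batch": [d.batch for d in design],
            "library_size": [d.library_size for d in design],
        }
    ).to_csv(path, sep="\t", index=False)


def compute_cpm(
    counts: pd.DataFrame, design: Sequence[SampleDesign]
) -> pd.DataFrame:
    """Counts-per-million: counts * 1e6 / library_size, per sample."""
    lib = {d.sample_id: d.library_size for d in design}
    missing = [c for c in counts.columns if c not in lib]
    if missing:
        raise DataError(f"library sizes missing for samples: {missing}")
    if any(lib[c] == 0 for c in counts.columns):
        raise DataError("zero library size")
    sizes = pd.Series({c: lib[c] for c in counts.columns}, dtype=float)
    return counts * 1e6 / sizes
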