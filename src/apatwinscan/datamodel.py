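"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout; a cleavage site is the
0-based position of the last transcribed base before the poly(A) tail.
Count matrices are plain :class:`pandas.DataFrame` objects with PAS
identifiers (``"<gene_id>|P"`` / ``"<gene_id>|D"``) as the index and
sample ids as columns; :func:`validate_count_matrix` checks the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

PROXIMAL = "P"
DISTAL = "D"


class DataError(ValueError):
    """Malformed input data (bad file contents, invariant violations)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: strand, exon structure and the CDS end.

    ``cds_end`` is the genomic coordinate (0-based) of the last coding base
    in *transcription* order — on the minus strand this is the leftmost CDS
    base. ``None`` for non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be '+' or '-'")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if not exons:
            raise DataError(f"gene {self.gene_id}: no exons")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise DataError(
                    f"gene {self.gene_id}: overlapping exons ({s0},{e0}) and ({s1},{e1})"
                )
        for s, e in exons:
            if s >= e:
                raise DataError(f"gene {self.gene_id}: empty exon ({s},{e})")
        object.__setattr__(self, "exons", exons)
        if self.cds_end is not None and not any(
            s <= self.cds_end < e for s, e in exons
        ):
            raise DataError(
                f"gene {self.gene_id}: cds_end {self.cds_end} outside all exons"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1

    def contains(self, site: int) -> bool:
        s, e = self.span
        return s <= site < e

    def is_downstream_of_cds(self, site: int) -> Optional[bool]:
        """True if *site* lies strictly downstream of the CDS end in
        transcription order; None when the gene has no CDS end."""
        if self.cds_end is None:
            return None
        return site > self.cds_end if self.strand == "+" else site < self.cds_end


@dataclass(frozen=True)
class ReadEnd:
    """The 3'-most transcribed base of one aligned read."""

    chrom: str
    site: int
    strand: str
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if self.site < 0:
            raise DataError(f"read end at negative coordinate {self.site}")
        if self.strand not in ("+", "-"):
            raise DataError(f"read end strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    condition: str
    batch: str
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise DataError(
                f"sample {self.sample_id}: library_size must be positive"
            )


def design_frame(design: Sequence[SampleDesign]) -> pd.DataFrame:
    """Design table as a DataFrame indexed by sample id (two conditions)."""
    df = pd.DataFrame(
        {
            "condition": [d.condition for d in design],
            "batch": [d.batch for d in design],
            "library_size": [d.library_size for d in design],
        },
        index=pd.Index([d.sample_id for d in design], name="sample"),
    )
    if df.index.duplicated().any():
        raise DataError("duplicate sample ids in design")
    n_cond = df["condition"].nunique()
    if n_cond != 2:
        raise DataError(f"design must have exactly two condition levels, got {n_cond}")
    return df


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise DataError(f"duplicate PAS id {dup!r} in count matrix")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise DataError(f"duplicate sample id {dup!r} in count matrix")
    if counts.isna().any().any():
        r = counts.index[counts.isna().any(axis=1)][0]
        c = counts.columns[counts.isna().any(axis=0)][0]
        raise DataError(f"missing count at row {r!r}, column {c!r}")
    if (counts.to_numpy() < 0).any():
        raise DataError("negative entry in count matrix")
    return counts


@dataclass
class PASCluster:
    """One called poly(A) site: clustered read 3'-end positions."""

    chrom: str
    strand: str
    cleavage_site: int
    positions: dict[int, int]  # member position -> pooled deduped count
    sample_counts: dict[str, int]  # sample -> deduped count

    @property
    def total_count(self) -> int:
        return sum(self.sample_counts.values())

    @property
    def span(self) -> tuple[int, int]:
        pos = sorted(self.positions)
        return pos[0], pos[-1] + 1

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.cleavage_site}:{self.strand}"


@dataclass
class PASRecord:
    """A gene-assigned PAS with its proximal/distal label and counts."""

    gene_id: str
    label: str  # PROXIMAL or DISTAL
    chrom: str
    strand: str
    cleavage_site: int
    counts: dict[str, int]

    @property
    def pas_id(self) -> str:
        return f"{self.gene_id}|{self.label}"


@dataclass
class TwoPASTable:
    """The per-gene unit of statistical testing: one proximal and one
    distal PAS with per-sample counts."""

    gene_id: str
    proximal: PASRecord
    distal: PASRecord

    def __post_init__(self) -> None:
        if self.proximal.cleavage_site == self.distal.cleavage_site:
            raise DataError(f"gene {self.gene_id}: proximal == distal site")

    def counts_frame(self, samples: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [self.proximal.counts.get(s, 0) for s in samples],
                [self.distal.counts.get(s, 0) for s in samples],
            ],
            index=[self.proximal.pas_id, self.distal.pas_id],
            columns=list(samples),
        )


@dataclass
class ShiftTest:
    """Per-gene interaction LRT result.

    ``log2_ratio_change`` is log2 of [(proximal/distal) usage ratio in
    condition B] over [the same ratio in condition A]; positive values mean
    the proximal PAS gained relative use in condition B.
    """

    gene_id: str
    lrt_statistic: float
    p_value: float
    interaction_coef: float
    log2_ratio_change: float
    converged: bool = True
    q_value: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> str:
        return "proximal" if self.log2_ratio_change > 0 else "distal"


@dataclass
class ShiftClassification:
    gene_id: str
    major_pas_A: Optional[str]
    major_pas_B: Optional[str]
    major_switch: bool
    apa_type: Optional[str]  # "UTR-APA" | "CDS-APA" | None
    direction: str


@dataclass(frozen=True)
class MotifHit:
    """A UGUA or twin-UGUA occurrence relative to a cleavage site.

    ``start_distance`` counts bases from the motif's first base to the
    cleavage site (the base immediately 5' of the cleavage site has
    distance 1).
    """

    kind: str  # "single" | "twin" | "twin_restricted"
    sequence: str  # RNA alphabet
    start: int  # 0-based index in the scanned sequence
    start_distance: int
    spacer_base: Optional[str] = None


@dataclass
class CandidateGene:
    gene_id: str
    loss_of_use_pas: str
    twin_hits: tuple[MotifHit, ...]
    other_ugua_count: int
    twin_distance: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.twin_hits:
            raise DataError(
                f"candidate {self.gene_id} must carry at least one twin hit"
            )
        self.twin_distance = min(h.start_distance for h in self.twin_hits)
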