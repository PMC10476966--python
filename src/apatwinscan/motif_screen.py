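"""UGUA and twin-UGUA motif scanning near cleavage sites, and the
candidate screen combining motif asymmetry with APA shift results.

The CFIm subunit NUDT21 recognizes the UGUA tetramer; a twin motif is
UGUANUGUA (two UGUA starts exactly five bases apart), and the restricted
twin UGUAYUGUA requires a pyrimidine spacer (C in human, U in mouse).
Distances are measured from a motif's first base to the cleavage site;
by default only the sequence upstream of the cleavage site is scanned,
where the UGUA element is enriched (roughly 40-100 bases upstream).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

from .datamodel import (
    CandidateGene,
    DISTAL,
    DataError,
    MotifHit,
    PASRecord,
    PROXIMAL,
    ShiftClassification,
    ShiftTest,
    TwoPASTable,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UGUA_DNA = "TGTA"
TWIN_SPACING = 5  # second UGUA starts exactly 5 bases after the first


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and collapse U to T; reject non-IUPAC-core characters."""
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in "ACGTN":
            raise DataError(f"illegal character {seq[i]!r} at position {i}")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_pas_window(
    genome: Mapping[str, str],
    pas: PASRecord,
    window: int = 100,
) -> tuple[str, bool]:
    """Transcribed-strand sequence of the *window* bases immediately
    upstream of (excluding) the cleavage-site base, 5'->3'.

    Returns (sequence, truncated_flag); the flag is set when the window
    runs off the chromosome edge.
    """
    if pas.chrom not in genome:
        raise DataError(f"chromosome {pas.chrom!r} absent from genome")
    chrom_seq = genome[pas.chrom]
    site = pas.cleavage_site
    if not 0 <= site < len(chrom_seq):
        raise DataError(
            f"cleavage site {site} outside chromosome {pas.chrom} "
            f"(length {len(chrom_seq)})"
        )
    if pas.strand == "+":
        start = max(0, site - window)
        seq = chrom_seq[start:site]
        truncated = site - window < 0
    else:
        end = min(len(chrom_seq), site + 1 + window)
        seq = reverse_complement(chrom_seq[site + 1 : end])
        truncated = site + 1 + window > len(chrom_seq)
    return seq, truncated


def scan_ugua_motifs(seq: str) -> list[MotifHit]:
    """Enumerate all single, twin, and restricted-twin UGUA hits.

    The cleavage site is anchored at the sequence 3' end: a motif starting
    at index i has start_distance len(seq) - i. Overlapping singles are
    allowed; a twin is emitted for every pair of UGUA starts (i, i+5).
    """
    s = normalize_seq(seq)
    L = len(s)
    starts = [i for i in range(L - 3) if s[i : i + 4] == UGUA_DNA]
    start_set = set(starts)
    hits: list[MotifHit] = []
    for i in starts:
        hits.append(
            MotifHit(
                kind="single",
                sequence=to_rna(s[i : i + 4]),
                start=i,
                start_distance=L - i,
            )
        )
        j = i + TWIN_SPACING
        if j in start_set:
            spacer = s[i + 4]
            kind = "twin_restricted" if spacer in ("C", "T") else "twin"
            hits.append(
                MotifHit(
                    kind=kind,
                    sequence=to_rna(s[i : i + 9]),
                    start=i,
                    start_distance=L - i,
                    spacer_base=to_rna(spacer),
                )
            )
    return hits


def hits_in_window(hits: Sequence[MotifHit], window: int) -> list[MotifHit]:
    """A motif counts as in-window iff its first base lies within the
    window (start_distance <= window)."""
    return [h for h in hits if h.start_distance <= window]


def twin_hits(hits: Sequence[MotifHit], restricted: bool = False) -> list[MotifHit]:
    kinds = {"twin_restricted"} if restricted else {"twin", "twin_restricted"}
    return [h for h in hits if h.kind in kinds]


def single_hits(hits: Sequence[MotifHit]) -> list[MotifHit]:
    return [h for h in hits if h.kind == "single"]


def loss_of_use_pas(test: ShiftTest) -> str:
    """The PAS whose relative usage decreased in condition B: the distal
    PAS when the proximal/distal ratio went up, else the proximal."""
    return DISTAL if test.log2_ratio_change > 0 else PROXIMAL


def screen_twin_candidates(
    results: Sequence[tuple[TwoPASTable, ShiftTest, Optional[ShiftClassification]]],
    genome: Mapping[str, str],
    window: int = 100,
    require_major_switch: bool = True,
    restricted: bool = False,
    strict_exclusion: bool = False,
) -> list[CandidateGene]:
    """Screen shifted genes for twin-UGUA motif asymmetry.

    A candidate is a significant gene (with a major-PAS switch when
    required) carrying at least one twin UGUA within *window* bases
    upstream of the loss-of-use cleavage site and no twin in the other
    PAS's window (strict mode excludes any single UGUA there too).
    """
    candidates: list[CandidateGene] = []
    for gene, test, classification in results:
        if not test.significant:
            continue
        if require_major_switch:
            if classification is None or not classification.major_switch:
                continue
        loss = loss_of_use_pas(test)
        loss_rec = gene.proximal if loss == PROXIMAL else gene.distal
        other_rec = gene.distal if loss == PROXIMAL else gene.proximal
        try:
            loss_seq, _ = extract_pas_window(genome, loss_rec, window)
            other_seq, _ = extract_pas_window(genome, other_rec, window)
        except DataError as exc:
            warnings.warn(f"gene {gene.gene_id} skipped: {exc}")
            continue
        loss_twins = hits_in_window(
            twin_hits(scan_ugua_motifs(loss_seq), restricted), window
        )
        other_all = scan_ugua_motifs(other_seq)
        other_excluded = (
            hits_in_window(single_hits(other_all), window)
            if strict_exclusion
            else hits_in_window(twin_hits(other_all, restricted), window)
        )
        if loss_twins and not other_excluded:
            candidates.append(
                CandidateGene(
                    gene_id=gene.gene_id,
                    loss_of_use_pas=loss,
                    twin_hits=tuple(loss_twins),
                    other_ugua_count=len(hits_in_window(single_hits(other_all), window)),
                )
            )
    return candidates


def mutate_ugua_to_uggg(seq: str, which: "Sequence[int] | str" = "all") -> str:
    """Replace selected UGUA occurrences with UGGG (the substitution known
    to abolish CFIm binding). *which* is 'all' or a list of UGUA start
    indices; length and alphabet (RNA/DNA, case) are preserved."""
    s = normalize_seq(seq)
    is_rna = "U" in seq.upper()
    starts = [i for i in range(len(s) - 3) if s[i : i + 4] == UGUA_DNA]
    if which == "all":
        chosen = starts
    else:
        chosen = list(which)
        bad = [i for i in chosen if i not in starts]
        if bad:
            raise DataError(f"positions {bad} are not UGUA starts")
    out = list(seq)
    repl = "UGGG" if is_rna else "TGGG"
    for i in chosen:
        for k, c in enumerate(repl):
            out[i + k] = c
    return "".join(out)
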