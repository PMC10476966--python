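"""Synthetic fixture generation with the statistical structure the
analysis assumes.

The generator emulates 3'-end CLIP-style profiling of two-PAS genes:
per-gene negative-binomial counts for a proximal and a distal poly(A)
site across replicated samples of two conditions (with batch effects and
a condition x PAS interaction on the shifted genes), read 3'-ends
scattered within +/-5 nt of each true cleavage site, and cleavage-site-
proximal sequence windows with twin-UGUA motifs planted upstream of the
loss-of-use PAS of designated candidate genes. Every other window is
rejection-sampled to contain no UGUA at all, so the downstream motif
screen has an exact truth set.

Read scatter uses a deterministic balanced offset cycle (0 strictly
modal, support +/-5 nt) rather than i.i.d. uniform draws: this keeps the
true cleavage site the modal position for every read count, so cluster
calling recovers simulated sites and counts exactly while still having
to merge an 11-position spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as io_mod
from .datamodel import (
    DISTAL,
    DataError,
    GeneModel,
    PROXIMAL,
    SampleDesign,
    design_frame,
)
from .motif_screen import normalize_seq, reverse_complement

TWIN_MOTIF_HUMAN = "UGUACUGUA"
TWIN_MOTIF_MOUSE = "UGUAUUGUA"


@dataclass
class SimulationConfig:
    """Study conditions for the simulated two-PAS experiment.

    delta_log2 is the interaction effect: the log2 change of the
    proximal/distal usage ratio between conditions for shifted genes.
    dispersion is the NB phi with Var = mu + phi mu^2.
    """

    n_genes: int = 200
    n_shifted: int = 20
    delta_log2: float = 2.0
    mean_gene_count: float = 200.0
    dispersion: float = 0.1
    replicates_per_condition: int = 3
    batch_effect_sd: float = 0.1
    library_sizes: Optional[Sequence[int]] = None
    pas_window: int = 150
    motif_distance: int = 50
    gc_content: float = 0.45
    seed: int = 0
    n_motif_candidates: int = 6
    candidate_p_fraction: float = 0.30
    twin_motif: str = TWIN_MOTIF_HUMAN
    abundance_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_shifted > self.n_genes:
            raise DataError("n_shifted must not exceed n_genes")
        if self.dispersion <= 0:
            raise DataError("dispersion must be positive")
        if not 0 < self.gc_content < 1:
            raise DataError("gc_content must be in (0, 1)")
        if 9 + self.motif_distance > self.pas_window:
            raise DataError("motif_distance + 9 must fit inside pas_window")
        if self.n_motif_candidates > self.n_shifted:
            raise DataError("n_motif_candidates must not exceed n_shifted")


def make_design(config: SimulationConfig) -> list[SampleDesign]:
    """Two conditions A/B with r replicates each; batches alternate within
    each condition (balanced across conditions) when r >= 2."""
    r = config.replicates_per_condition
    if r < 1:
        raise DataError("replicates_per_condition must be >= 1")
    n = 2 * r
    if config.library_sizes is None:
        libs = [1_000_000] * n
    else:
        libs = list(config.library_sizes)
        if len(libs) != n:
            raise DataError(f"library_sizes must have {n} entries")
    design = []
    i = 0
    for cond in ("A", "B"):
        for rep in range(r):
            batch = f"b{rep % 2}" if r >= 2 else "b0"
            design.append(SampleDesign(f"{cond}{rep + 1}", cond, batch, libs[i]))
            i += 1
    return design


def _gene_parameters(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, ns = config.n_genes, config.n_shifted
    nc = min(config.n_motif_candidates, ns)
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]
    is_shifted = np.zeros(n, dtype=bool)
    is_shifted[:ns] = True
    is_candidate = np.zeros(n, dtype=bool)
    is_candidate[:nc] = True
    p_frac = rng.uniform(0.2, 0.8, size=n)
    # candidates: fixed minority-proximal baseline with a positive ratio
    # shift, so the major PAS switches D -> P and loss-of-use is distal
    p_frac[:nc] = config.candidate_p_fraction
    delta = np.zeros(n)
    delta[:nc] = config.delta_log2
    signs = np.where(np.arange(ns - nc) % 2 == 0, 1.0, -1.0)
    delta[nc:ns] = signs * config.delta_log2
    rel = rng.lognormal(
        mean=-0.5 * config.abundance_log_sd**2,
        sigma=config.abundance_log_sd,
        size=n,
    )
    loss = np.where(is_shifted, np.where(delta > 0, DISTAL, PROXIMAL), "")
    return pd.DataFrame(
        {
            "delta_log2": delta,
            "p_frac": p_frac,
            "is_shifted": is_shifted,
            "is_candidate": is_candidate,
            "loss_of_use_pas": loss,
            "rel_abundance": rel,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_counts(
    config: SimulationConfig,
    design: Optional[Sequence[SampleDesign]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the PAS x sample NB count matrix and its truth table.

    log mu_gks = log(lib_s) + a_g + b_gk + batch_gb
                 + delta_g * ln2 * 1[condition B] * 1[proximal],
    counts ~ NB(mu, phi).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if design is None:
        design = make_design(config)
    ddf = design_frame(design)
    truth = _gene_parameters(config, rng)
    n = config.n_genes
    libs = ddf["library_size"].to_numpy(dtype=float)
    mean_lib = libs.mean()
    cond_b = (ddf["condition"] == sorted(ddf["condition"].unique())[1]).to_numpy()
    batches = sorted(ddf["batch"].unique())
    batch_idx = ddf["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    batch_eff = np.zeros((n, len(batches)))
    if len(batches) > 1 and config.batch_effect_sd > 0:
        batch_eff[:, 1:] = rng.normal(
            0.0, config.batch_effect_sd, size=(n, len(batches) - 1)
        )

    a = config.mean_gene_count / mean_lib * truth["rel_abundance"].to_numpy()
    p = truth["p_frac"].to_numpy()
    delta_mult = 2.0 ** truth["delta_log2"].to_numpy()

    # mu[gene, pas, sample]
    mu = np.empty((n, 2, len(design)))
    base = libs[None, :] * a[:, None] * np.exp(batch_eff[:, batch_idx])
    mu[:, 0, :] = base * p[:, None]
    mu[:, 1, :] = base * (1.0 - p)[:, None]
    mu[:, 0, :] *= np.where(cond_b[None, :], delta_mult[:, None], 1.0)
    if not np.all(np.isfinite(mu)):
        raise DataError("non-finite mean in count simulation")
    phi = config.dispersion
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))

    rows, data = [], []
    for i, g in enumerate(truth.index):
        rows += [f"{g}|{PROXIMAL}", f"{g}|{DISTAL}"]
        data += [counts[i, 0, :], counts[i, 1, :]]
    counts_df = pd.DataFrame(
        np.array(data), index=pd.Index(rows, name="pas_id"), columns=ddf.index
    )
    return counts_df, truth.drop(columns=["rel_abundance"])


# ---------------------------------------------------------------------------
# sequence planting


def _random_bases(
    length: int, gc: float, rng: np.random.Generator
) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def _ugua_starts(s: str) -> set[int]:
    return {i for i in range(len(s) - 3) if s[i : i + 4] == "TGTA"}


def plant_motif_sequence(
    length: int,
    gc: float,
    motif: Optional[str],
    offset_upstream: int = 0,
    rng: "np.random.Generator | int | None" = None,
    max_tries: int = 10_000,
) -> str:
    """A random DNA window whose 3' end abuts the cleavage site.

    When *motif* is given, its first base sits *offset_upstream* bases
    upstream of the cleavage site and the background is rejection-sampled
    so the planted motif's UGUAs are the only ones present. When *motif*
    is None the whole window is UGUA-free.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    motif_dna = normalize_seq(motif) if motif is not None else None
    if motif_dna is not None:
        if offset_upstream < len(motif_dna) or offset_upstream > length:
            raise DataError(
                f"motif of length {len(motif_dna)} does not fit at "
                f"offset {offset_upstream} in a {length}-base window"
            )
        pos = length - offset_upstream
        expected = {pos + i for i in _ugua_starts(motif_dna)}
    for _ in range(max_tries):
        seq = _random_bases(length, gc, rng)
        if motif_dna is not None:
            seq[pos : pos + len(motif_dna)] = list(motif_dna)
        s = "".join(seq)
        found = _ugua_starts(s)
        if motif_dna is None:
            if not found:
                return s
        elif found == expected:
            return s
    raise DataError("rejection sampling failed to produce a clean window")


# ---------------------------------------------------------------------------
# full fixture bundle

_JITTER_NONZERO = np.array([-5, 5, -4, 4, -3, 3, -2, 2, -1, 1])
JITTER_MAX = 5


def jitter_offsets(n: int) -> np.ndarray:
    """Deterministic balanced scatter offsets for n reads: support +/-5,
    with 0 strictly modal for every n (so the true site stays the mode)."""
    idx = np.arange(n)
    off = np.zeros(n, dtype=int)
    mask = (idx >= 2) & ((idx - 2) % 2 == 0)
    off[mask] = _JITTER_NONZERO[((idx[mask] - 2) // 2) % len(_JITTER_NONZERO)]
    return off


@dataclass
class GeneLocus:
    gene: GeneModel
    p_site: int
    d_site: int

    def site(self, label: str) -> int:
        return self.p_site if label == PROXIMAL else self.d_site


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    design: list[SampleDesign]
    genes: list[GeneModel]
    genome: dict[str, str]
    counts: pd.DataFrame
    truth: pd.DataFrame
    reads: dict[str, pd.DataFrame]
    loci: dict[str, GeneLocus]

    def write(self, outdir: "str | Path") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.bed",
            "design": outdir / "design.tsv",
            "counts": outdir / "counts.tsv",
            "truth": outdir / "truth.tsv",
        }
        io_mod.write_fasta(self.genome, paths["genome"])
        io_mod.write_gene_annotation(self.genes, paths["genes"])
        io_mod.write_design(self.design, paths["design"])
        io_mod.write_count_table(self.counts, paths["counts"])
        self.truth.to_csv(paths["truth"], sep="\t")
        for sample, frame in self.reads.items():
            p = outdir / f"reads_{sample}.bed"
            io_mod.write_read_ends(frame, p)
            paths[f"reads_{sample}"] = p
        return paths


def _gene_geometry(index: int, gene_id: str, config: SimulationConfig) -> GeneLocus:
    W = config.pas_window
    spacing = W + 100
    chrom = f"chr_{gene_id}"
    strand = "+" if index % 2 == 0 else "-"
    cds_apa = index % 3 == 0
    p_plus, d_plus = 600, 600 + spacing
    chrom_len = d_plus + 61
    cds_plus = p_plus + 50 if cds_apa else 400
    if strand == "+":
        p_site, d_site, cds_end = p_plus, d_plus, cds_plus
        exons = ((100, d_site + 1),)
    else:
        p_site = chrom_len - 1 - p_plus
        d_site = chrom_len - 1 - d_plus
        cds_end = chrom_len - 1 - cds_plus
        exons = ((d_site, chrom_len - 100),)
    gene = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, cds_end=cds_end
    )
    return GeneLocus(gene=gene, p_site=p_site, d_site=d_site)


def _chrom_length(config: SimulationConfig) -> int:
    return 600 + (config.pas_window + 100) + 61


def simulate_dataset(
    config: SimulationConfig, outdir: "str | Path | None" = None
) -> SimulatedDataset:
    """Generate the full fixture bundle: genome FASTA, gene models, BED6
    read ends per sample, design table, count matrix and truth table."""
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    counts, truth = simulate_counts(config, design, rng)

    loci: dict[str, GeneLocus] = {}
    genome: dict[str, str] = {}
    chrom_len = _chrom_length(config)
    W = config.pas_window
    apa_types = []
    for i, gene_id in enumerate(truth.index):
        locus = _gene_geometry(i, gene_id, config)
        loci[gene_id] = locus
        apa_types.append("CDS-APA" if i % 3 == 0 else "UTR-APA")
        bg = "".join(_random_bases(chrom_len, config.gc_content, rng))
        seq = np.array(list(bg))
        plant_in = (
            truth.loc[gene_id, "loss_of_use_pas"]
            if truth.loc[gene_id, "is_candidate"]
            else None
        )
        for label in (PROXIMAL, DISTAL):
            motif = config.twin_motif if label == plant_in else None
            window = plant_motif_sequence(
                W, config.gc_content, motif, config.motif_distance, rng
            )
            site = locus.site(label)
            if locus.gene.strand == "+":
                seq[site - W : site] = list(window)
            else:
                rc = reverse_complement(window)
                seq[site + 1 : site + 1 + W] = list(rc)
        genome[locus.gene.chrom] = "".join(seq)

    truth = truth.copy()
    truth["apa_type"] = apa_types
    truth["strand"] = [loci[g].gene.strand for g in truth.index]
    truth["p_site"] = [loci[g].p_site for g in truth.index]
    truth["d_site"] = [loci[g].d_site for g in truth.index]
    truth["motif_planted"] = truth["is_candidate"]

    reads: dict[str, pd.DataFrame] = {}
    for sample in counts.columns:
        chroms, sites, strands, umis = [], [], [], []
        for gene_id in truth.index:
            locus = loci[gene_id]
            sign = 1 if locus.gene.strand == "+" else -1
            for label in (PROXIMAL, DISTAL):
                c = int(counts.loc[f"{gene_id}|{label}", sample])
                if c == 0:
                    continue
                offs = jitter_offsets(c)
                pos = locus.site(label) + sign * offs
                chroms.extend([locus.gene.chrom] * c)
                sites.extend(pos.tolist())
                strands.extend([locus.gene.strand] * c)
                umis.extend(
                    f"{sample}:{gene_id}:{label}:{j}" for j in range(c)
                )
        reads[sample] = pd.DataFrame(
            {"chrom": chroms, "site": sites, "strand": strands, "umi": umis}
        )

    ds = SimulatedDataset(
        config=config,
        design=design,
        genes=[loci[g].gene for g in truth.index],
        genome=genome,
        counts=counts,
        truth=truth,
        reads=reads,
        loci=loci,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds
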