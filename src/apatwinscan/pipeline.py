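"""End-to-end orchestration: simulate -> call PAS -> test shifts ->
classify -> screen motifs, with a single declarative config, structured
logging and a machine-readable run summary."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as io_mod
from .apa_stats import test_apa_shifts, tmm_factors
from .datamodel import DataError, ShiftTest, design_frame
from .motif_screen import screen_twin_candidates
from .pas_calling import build_two_pas_table, call_pas_sites, two_pas_count_matrix
from .shift_classify import classification_frame, classify_shift
from .synthetic import SimulationConfig, simulate_dataset

log = logging.getLogger("apatwinscan")


@dataclass
class PipelineConfig:
    """All tunables of the screen in one place.

    Defaults equal the printed decision thresholds of the analysis this
    reproduces: alpha 0.05, 2-fold ratio change, >50% major PAS, 100-bp
    motif window.
    """

    outdir: str = "apatwinscan_run"
    # inputs (ignored when simulate=True)
    reads: dict = field(default_factory=dict)  # sample -> BED6 path
    genes: Optional[str] = None
    genome: Optional[str] = None
    design: Optional[str] = None
    # simulation
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    # PAS calling
    gap: int = 24
    dedup: str = "umi"
    min_minor_fraction: float = 0.05
    min_gene_count: int = 20
    # statistics
    alpha: float = 0.05
    fold: float = 2.0
    dispersion: "str | float" = "common"
    fdr: str = "storey"
    # motif screen
    window: int = 100
    require_major_switch: bool = True
    restricted: bool = False
    strict_exclusion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")
        if self.fold <= 1:
            raise DataError("fold must exceed 1")
        if self.window < 9:
            raise DataError("window must be at least 9 (one twin motif)")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_screen(config: PipelineConfig) -> dict:
    """Run the full screen; returns the machine-readable summary dict.

    Writes results.tsv, classification.tsv, candidates.tsv, summary.json
    and run.log under config.outdir. Identical config + seed gives a
    byte-identical summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    stage = "setup"
    try:
        log.info("config: %s", json.dumps(dataclasses.asdict(config), default=str))
        if config.simulate:
            stage = "simulate"
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", config.seed)
            sim = simulate_dataset(SimulationConfig(**sim_kwargs))
            sim.write(outdir / "simulated")
            reads = sim.reads
            genes = sim.genes
            genome = sim.genome
            design = sim.design
        else:
            stage = "load"
            if not (config.reads and config.genes and config.genome and config.design):
                raise DataError(
                    "reads, genes, genome and design paths are required "
                    "when simulate is disabled"
                )
            reads = {
                s: io_mod.read_read_ends(p, as_frame=True)
                for s, p in config.reads.items()
            }
            genes = io_mod.read_gene_annotation(config.genes)
            genome = io_mod.read_fasta(config.genome)
            design = io_mod.read_design(config.design)
        ddf = design_frame(design)
        log.info("loaded %d genes, %d samples", len(genes), len(ddf))

        stage = "call-pas"
        clusters = call_pas_sites(reads, gap=config.gap, dedup=config.dedup)
        tables, call_log = build_two_pas_table(
            clusters,
            genes,
            min_minor_fraction=config.min_minor_fraction,
            min_gene_count=config.min_gene_count,
        )
        log.info("called %d clusters; %d two-PAS genes (%s)",
                 len(clusters), len(tables), call_log)
        counts = two_pas_count_matrix(tables, list(ddf.index))
        io_mod.write_count_table(counts, outdir / "counts.tsv")

        stage = "test-shift"
        norm = tmm_factors(counts)
        results = test_apa_shifts(
            counts,
            ddf,
            alpha=config.alpha,
            fold=config.fold,
            dispersion=config.dispersion,
            fdr=config.fdr,
            norm=norm,
        )
        results.to_csv(outdir / "results.tsv", sep="\t")
        log.info("tested %d genes, %d significant",
                 len(results), int(results["significant"].sum()))

        stage = "classify"
        gene_by_id = {g.gene_id: g for g in genes}
        tests = {}
        classifications = []
        pairs = []
        for t in tables:
            row = results.loc[t.gene_id]
            st = ShiftTest(
                gene_id=t.gene_id,
                lrt_statistic=float(row["lrt_statistic"]),
                p_value=float(row["p_value"]),
                interaction_coef=float(row["interaction_coef"]),
                log2_ratio_change=float(row["log2_ratio_change"]),
                converged=bool(row["converged"]),
                q_value=float(row["q_value"]),
                significant=bool(row["significant"]),
            )
            tests[t.gene_id] = st
            c = classify_shift(t, gene_by_id[t.gene_id], st, ddf, norm)
            classifications.append(c)
            pairs.append((t, st, c))
        cframe = classification_frame(classifications)
        cframe.to_csv(outdir / "classification.tsv", sep="\t")

        stage = "screen-motifs"
        candidates = screen_twin_candidates(
            pairs,
            genome,
            window=config.window,
            require_major_switch=config.require_major_switch,
            restricted=config.restricted,
            strict_exclusion=config.strict_exclusion,
        )
        cand_frame = pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in candidates],
                "loss_of_use_pas": [c.loss_of_use_pas for c in candidates],
                "twin_sequence": [c.twin_hits[0].sequence for c in candidates],
                "twin_distance": [c.twin_distance for c in candidates],
                "other_window_ugua": [c.other_ugua_count for c in candidates],
            }
        ).set_index("gene_id")
        cand_frame.to_csv(outdir / "candidates.tsv", sep="\t")

        stage = "summary"
        sig = results[results["significant"]]
        summary = {
            "seed": config.seed,
            "n_clusters": len(clusters),
            "n_genes_tested": int(len(results)),
            "n_significant": int(len(sig)),
            "n_proximal_shifts": int((sig["direction"] == "proximal").sum()),
            "n_distal_shifts": int((sig["direction"] == "distal").sum()),
            "n_major_switch": int(cframe["major_switch"].sum()),
            "n_candidates": len(candidates),
            "candidates": sorted(c.gene_id for c in candidates),
            "dispersion": results.attrs.get("dispersion"),
        }
        payload = json.dumps(summary, sort_keys=True, indent=2)
        summary["digest"] = hashlib.sha256(payload.encode()).hexdigest()
        (outdir / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2)
        )
        log.info("done in %.1fs: %s", time.time() - t0, summary)
        return summary
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
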