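"""Functional filtering of APA shifts: major-PAS determination, the
major-switch flag, and UTR- vs CDS-APA classification.

A shift is classified CDS-APA when the two isoforms differ in coding
sequence, i.e. when at least one cleavage site does not lie strictly
downstream (in transcription order) of the CDS end; a site exactly at the
CDS end counts as not downstream. UTR-APA shifts change only the 3' UTR.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DISTAL,
    PROXIMAL,
    GeneModel,
    ShiftClassification,
    ShiftTest,
    TwoPASTable,
)
from .apa_stats import NormalizationFactors

UTR_APA = "UTR-APA"
CDS_APA = "CDS-APA"


def determine_major_pas(
    gene: TwoPASTable,
    condition: str,
    design_df: pd.DataFrame,
    norm: Optional[NormalizationFactors] = None,
) -> tuple[Optional[str], float, float]:
    """The PAS holding >50% of the condition's pooled two-PAS total.

    Counts are pooled across the condition's replicates after TMM/library
    scaling (raw pooling when *norm* is None). Returns
    (major_label_or_None, fraction_P, fraction_D); an exact 50/50 split or
    a zero total yields a None major PAS.
    """
    samples = design_df.index[design_df["condition"] == condition]
    if norm is not None:
        eff = norm.effective_library_sizes
        scale = np.exp(np.mean(np.log(eff.to_numpy(dtype=float))))
        weights = {s: scale / eff[s] for s in samples}
    else:
        weights = {s: 1.0 for s in samples}
    p = sum(gene.proximal.counts.get(s, 0) * weights[s] for s in samples)
    d = sum(gene.distal.counts.get(s, 0) * weights[s] for s in samples)
    tot = p + d
    if tot == 0:
        warnings.warn(f"gene {gene.gene_id}: zero total in condition {condition}")
        return None, float("nan"), float("nan")
    fp, fd = p / tot, d / tot
    if fp > 0.5:
        return PROXIMAL, fp, fd
    if fd > 0.5:
        return DISTAL, fp, fd
    return None, fp, fd  # exact tie


def classify_shift(
    gene: TwoPASTable,
    model: GeneModel,
    test: ShiftTest,
    design_df: pd.DataFrame,
    norm: Optional[NormalizationFactors] = None,
) -> ShiftClassification:
    """Classify one tested gene: major PAS per condition, switch flag, and
    UTR- vs CDS-APA type."""
    cond_a, cond_b = sorted(design_df["condition"].unique())
    major_a, *_ = determine_major_pas(gene, cond_a, design_df, norm)
    major_b, *_ = determine_major_pas(gene, cond_b, design_df, norm)
    switch = major_a is not None and major_b is not None and major_a != major_b

    if model.cds_end is None:
        warnings.warn(
            f"gene {gene.gene_id}: no CDS end; APA type undefined"
        )
        apa_type = None
    else:
        down_p = model.is_downstream_of_cds(gene.proximal.cleavage_site)
        down_d = model.is_downstream_of_cds(gene.distal.cleavage_site)
        apa_type = UTR_APA if (down_p and down_d) else CDS_APA

    return ShiftClassification(
        gene_id=gene.gene_id,
        major_pas_A=major_a,
        major_pas_B=major_b,
        major_switch=switch,
        apa_type=apa_type,
        direction=test.direction,
    )


def filter_functional_shifts(
    classified: Sequence[tuple[ShiftClassification, ShiftTest]],
) -> list[ShiftClassification]:
    """Keep genes that are significant, switched their major PAS, and are
    CDS-APA — the filter for shifts likely to alter the protein product."""
    return [
        c
        for c, t in classified
        if t.significant and c.major_switch and c.apa_type == CDS_APA
    ]


def classification_frame(
    classified: Sequence[ShiftClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classified],
            "major_A": [c.major_pas_A or "tie" for c in classified],
            "major_B": [c.major_pas_B or "tie" for c in classified],
            "major_switch": [c.major_switch for c in classified],
            "apa_type": [c.apa_type or "NA" for c in classified],
            "direction": [c.direction for c in classified],
        }
    ).set_index("gene_id")
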