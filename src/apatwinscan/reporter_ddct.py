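"""Relative PAS usage from qPCR Ct tables by the ddCt method.

In the tandem-PAS reporter assay the test PAS sits upstream of a constant
bGH PAS; the distal bGH-derived isoform is the within-sample normalizer,
and usage is expressed as 2^(-ddCt) relative to a reference sample
(reference usage == 1). A mode switch supports normalization against an
endogenous control target instead (ACTB/Rplp0-style mRNA quantification).
Assumes ideal 2-fold-per-cycle amplification efficiency.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datamodel import DataError

REQUIRED_COLUMNS = ("sample", "target", "ct")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"Ct table missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or ~np.isfinite(ct).all():
        raise DataError("non-finite Ct value in table")
    return table.assign(ct=ct)


def relative_pas_usage_ddct(
    table: pd.DataFrame,
    reference_sample: str,
    test_target: str = "test_pas_isoform",
    normalizer_target: str = "distal_bgh_isoform",
) -> pd.DataFrame:
    """ddCt relative usage per sample.

    Replicate Ct values are averaged arithmetically per (sample, target);
    dCt = mean Ct(test) - mean Ct(normalizer), ddCt = dCt - dCt(reference),
    usage = 2^(-ddCt). The returned frame carries usage and a propagated
    standard deviation (independent-error propagation of replicate SDs
    through dCt, on the usage scale).
    """
    table = _validate(table)
    targets = set(table["target"].unique())
    if normalizer_target not in targets:
        raise DataError(f"normalizer target {normalizer_target!r} absent from table")
    if test_target not in targets:
        raise DataError(f"test target {test_target!r} absent from table")
    agg = table.groupby(["sample", "target"])["ct"].agg(["mean", "std", "count"])
    samples = sorted(table["sample"].unique())
    if reference_sample not in samples:
        raise DataError(f"reference sample {reference_sample!r} absent from table")

    def _cell(sample: str, target: str) -> tuple[float, float]:
        try:
            row = agg.loc[(sample, target)]
        except KeyError:
            raise DataError(f"sample {sample!r} lacks target {target!r}") from None
        sd = row["std"]
        sem2 = 0.0 if (row["count"] < 2 or not np.isfinite(sd)) else sd**2 / row["count"]
        return float(row["mean"]), float(sem2)

    dct = {}
    for s in samples:
        m_t, v_t = _cell(s, test_target)
        m_n, v_n = _cell(s, normalizer_target)
        dct[s] = (m_t - m_n, v_t + v_n)
    ref_dct, ref_var = dct[reference_sample]
    rows = []
    for s in samples:
        d, v = dct[s]
        ddct = d - ref_dct
        var = v + (0.0 if s == reference_sample else ref_var)
        usage = 2.0 ** (-ddct)
        usage_sd = usage * math.log(2) * math.sqrt(var)
        rows.append((s, ddct, usage, usage_sd))
    return pd.DataFrame(
        rows, columns=["sample", "ddct", "relative_usage", "usage_sd"]
    ).set_index("sample")
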