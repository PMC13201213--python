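"""Length-normalized TE mRNA abundance per million transcripts.

Implements the quantification arithmetic applied to transcript-level count
tables (host mRNAs and TE consensus sequences quantified together): the
per-transcript read rate is ``count / length`` and abundances are rates
scaled to one million over all transcripts, host and TE alike (TPM-style).
Upstream read-level quantification is out of scope; counts are taken as
given, without effective-length correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["validate_counts", "tpm", "te_summary", "log_ratios"]


def validate_counts(table: pd.DataFrame) -> None:
    required = {"transcript_id", "class", "length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if table["transcript_id"].duplicated().any():
        raise ValueError("transcript ids must be unique")
    if (table["length"] <= 0).any():
        raise ValueError("transcript lengths must be positive")
    bad = set(table["class"]) - {"host", "TE"}
    if bad:
        raise ValueError(f"unknown transcript classes: {sorted(bad)}")


def tpm(table: pd.DataFrame, count_col: str = "count") -> pd.Series:
    """Per-transcript abundance: ``(count/length) * 1e6 / sum(count/length)``
    with host and TE transcripts sharing the denominator."""
    validate_counts(table)
    counts = table[count_col].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts / table["length"].to_numpy(dtype=float)
    total = rates.sum()
    if total <= 0:
        raise ValueError("all counts are zero; abundance undefined")
    return pd.Series(rates * 1e6 / total, index=table["transcript_id"], name=count_col)


def te_summary(table: pd.DataFrame, count_col: str = "count") -> pd.DataFrame:
    """Per-TE abundance plus the total over all TE transcripts."""
    abundance = tpm(table, count_col)
    te_rows = table[table["class"] == "TE"]
    per_te = abundance.loc[te_rows["transcript_id"]]
    out = per_te.rename("abundance").reset_index()
    total = pd.DataFrame(
        [{"transcript_id": "TE_total", "abundance": float(per_te.sum())}]
    )
    return pd.concat([out, total], ignore_index=True)


def log_ratios(
    table: pd.DataFrame,
    count_col_a: str = "count_a",
    count_col_b: str = "count_b",
    pseudo_abundance: float = 1.0,
) -> pd.DataFrame:
    """Per-TE log2 abundance ratio between two libraries of the same table.

    A pseudo-abundance (default 1 per-million unit) guards zeros so that a
    TE absent from both libraries reports a log-ratio of 0.
    """
    a = tpm(table, count_col_a)
    b = tpm(table, count_col_b)
    te_ids = table.loc[table["class"] == "TE", "transcript_id"]
    rows = []
    for tid in te_ids:
        la = float(a[tid]) + pseudo_abundance
        lb = float(b[tid]) + pseudo_abundance
        rows.append(
            {
                "transcript_id": tid,
                "abundance_a": float(a[tid]),
                "abundance_b": float(b[tid]),
                "log2_ratio": float(np.log2(lb / la)),
            }
        )
    return pd.DataFrame(rows)
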