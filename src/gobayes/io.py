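"""Tab-delimited evidence and posterior files.

Evidence files carry the output of a first-level Bayesian expression
analysis: one gene per line with its posterior probability of activity
and, optionally, the prior probability that analysis used (0.5 when the
column is absent, under which the evidence ratio reduces to the
posterior itself).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_evidence", "write_evidence"]

EVIDENCE_COLUMNS = ["gene_id", "posterior", "prior"]


def read_evidence(path) -> pd.DataFrame:
    """Read a gene evidence TSV: gene_id <TAB> posterior [<TAB> prior]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    if cols[:2] != ["gene_id", "posterior"]:
        raise ValueError(
            f"evidence file must start with columns gene_id, posterior; got {cols[:2]}"
        )
    if "prior" not in df.columns:
        df["prior"] = 0.5
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in evidence file: {dup!r}")
    bad = ~df["posterior"].between(0.0, 1.0)
    if bad.any():
        raise ValueError(
            f"posterior out of [0, 1] for gene {df.loc[bad, 'gene_id'].iloc[0]!r}"
        )
    return df[EVIDENCE_COLUMNS]


def write_evidence(df: pd.DataFrame, path) -> None:
    """Write a gene evidence TSV (prior column included when present)."""
    cols = [c for c in EVIDENCE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
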