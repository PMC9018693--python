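"""Relative mRNA expression from qPCR Ct values.

Expression is housekeeping-normalised on the cycle-threshold scale:
dCt = Ct(target) - mean(Ct(housekeeping)), and relative expression is
2^-dCt, so one extra cycle to threshold halves the inferred expression.
Technical replicates are averaged on the Ct scale before dCt.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import ExpressionRecord


def delta_ct_expression(
    ct_target: float, ct_housekeeping: Sequence[float]
) -> float:
    """2^-dCt relative expression for one sample/transcript.

    Raises on missing housekeeping values or non-positive Cts.
    """
    if ct_housekeeping is None or len(ct_housekeeping) == 0:
        raise ValueError("housekeeping Ct values are required")
    cts = [ct_target, *ct_housekeeping]
    if not all(np.isfinite(c) and c > 0 for c in cts):
        raise ValueError("all Ct values must be finite and positive")
    delta = ct_target - float(np.mean(ct_housekeeping))
    return float(2.0 ** (-delta))


def expression_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """Tidy per-sample relative-expression table."""
    rows = [
        {
            "sample_id": r.sample_id,
            "transcript": r.transcript,
            "ct_target": r.ct_target,
            "ct_housekeeping_mean": float(np.mean(r.ct_housekeeping)),
            "rel_expr": r.rel_expr,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def read_ct_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a Ct TSV with columns sample_id, transcript, ct, role.

    ``role`` is "target" or "housekeeping"; technical replicates (repeated
    rows) are averaged on the Ct scale. Housekeeping wells are shared
    across transcripts within a sample.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "transcript", "ct", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    records = []
    for sample_id, sdf in df.groupby("sample_id", sort=True):
        hk = tuple(sdf.loc[sdf.role == "housekeeping", "ct"])
        targets = sdf[sdf.role == "target"]
        for transcript, tdf in targets.groupby("transcript", sort=True):
            records.append(
                ExpressionRecord(
                    sample_id=str(sample_id),
                    transcript=str(transcript),
                    ct_target=float(tdf.ct.mean()),
                    ct_housekeeping=hk,
                )
            )
    return records


def write_expression_tsv(
    records: Iterable[ExpressionRecord], path: str | Path
) -> None:
    expression_table(records).to_csv(path, sep="\t")
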