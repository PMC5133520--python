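"""Collapsing of independent binary phenotype replicates.

Given m independent simulated disease-status replicates, an individual with
l positive replicates is a case under the *specific* definition when
l/m >= 0.5 and under the *sensitive* definition when l/m > 0.  The specific
definition narrows the case set as m grows; the sensitive one widens it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CollapsedPhenotype", "collapse"]

MODES = ("specific", "sensitive")


@dataclass
class CollapsedPhenotype:
    status: pd.Series  # binary, indexed by individual
    m: int
    mode: str
    source_replicate_ids: list[str]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.m != len(self.source_replicate_ids) or self.m < 1:
            raise ValueError("m must equal the number of source replicates and be >= 1")

    @property
    def case_count(self) -> int:
        return int(self.status.sum())


def collapse(
    replicates: pd.DataFrame,
    mode: str = "specific",
    m: int | None = None,
) -> CollapsedPhenotype:
    """Collapse the first ``m`` replicate columns into one case/control status.

    ``replicates`` is an individuals x R binary matrix; ``m`` defaults to all
    columns and otherwise takes the first ``m`` in column order (matching the
    convention of collapsing a numbered prefix of simulation replicates).
    The boundary l/m = 0.5 counts as a case under the specific mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if replicates.shape[0] == 0 or replicates.shape[1] == 0:
        raise ValueError("replicate matrix is empty")
    if m is None:
        m = replicates.shape[1]
    if not 1 <= m <= replicates.shape[1]:
        raise ValueError(f"m={m} outside 1..{replicates.shape[1]}")
    used = replicates.iloc[:, :m]
    values = used.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("replicate matrix must be binary")
    l = values.sum(axis=1)
    if mode == "specific":
        status = (l / m >= 0.5).astype(np.int8)
    else:
        status = (l > 0).astype(np.int8)
    return CollapsedPhenotype(
        status=pd.Series(status, index=replicates.index, name=f"{mode}_m{m}"),
        m=m,
        mode=mode,
        source_replicate_ids=list(used.columns),
    )
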