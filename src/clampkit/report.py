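"""Condition-level aggregation of per-cell metrics.

Collapses the long-format per-cell metrics table into condition
summaries (age_group × zt_window by default) with n, mean and standard
error of the mean — the hand-off point to any standard statistics tool;
hypothesis testing is intentionally left outside this package.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["summarize"]

logger = logging.getLogger(__name__)


def summarize(table: pd.DataFrame,
              group_keys: Sequence[str] = ("age_group", "zt_window")
              ) -> pd.DataFrame:
    """Per metric × condition: n, mean, SEM (sd/√n, sample sd).

    Missing (NaN) values are excluded and counted per group; conditions
    with no finite values for a metric are omitted with a warning. SEM
    is NaN for n < 2. The aggregation is permutation-invariant over
    input rows.
    """
    group_keys = list(group_keys)
    required = {"metric", "value", *group_keys}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"table lacks required columns: {sorted(missing_cols)}")

    rows = []
    for keys, grp in table.groupby(group_keys + ["metric"], dropna=False, sort=True):
        vals = pd.to_numeric(grp["value"], errors="coerce").to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_missing = vals.size - finite.size
        if n_missing:
            logger.info("condition %s metric %s: excluded %d missing values",
                        keys[:-1], keys[-1], n_missing)
        if finite.size == 0:
            logger.warning("condition %s metric %s: no finite values, omitted",
                           keys[:-1], keys[-1])
            continue
        mean = float(np.mean(finite))
        sem = float(np.std(finite, ddof=1) / np.sqrt(finite.size)) \
            if finite.size >= 2 else float("nan")
        row = dict(zip(group_keys, keys[:-1]))
        row.update(metric=keys[-1], n=int(finite.size), mean=mean, sem=sem,
                   n_missing=int(n_missing))
        rows.append(row)
    return pd.DataFrame(rows, columns=group_keys + ["metric", "n", "mean",
                                                    "sem", "n_missing"])
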