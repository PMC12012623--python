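"""Duration stratification shared by the generator and the severity scores."""

from __future__ import annotations

import numpy as np


def pool_duration_bins(durations, min_size: int = 5) -> np.ndarray:
    """Assign integer-year duration bins, pooling sparse bins.

    Durations are binned by whole years (``floor``); walking the bins in
    increasing order, adjacent bins are merged until every stratum holds at
    least ``min_size`` members (a trailing undersized remainder is merged
    into the last complete stratum).  Returns an integer stratum label per
    input element, labels increasing with duration.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("empty duration vector")
    if np.any(d < 0):
        raise ValueError("negative disease duration")
    years = np.floor(d).astype(int)
    uniq, counts = np.unique(years, return_counts=True)
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for b, c in zip(uniq, counts):
        cur.append(int(b))
        cur_n += int(c)
        if cur_n >= min_size:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    label_of = {b: i for i, grp in enumerate(groups) for b in grp}
    return np.asarray([label_of[y] for y in years], dtype=int)
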