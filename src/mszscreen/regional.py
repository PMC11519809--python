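"""Six-region expression-localization filter.

Emulates the RT-PCR screen across six dissected embryonic locations: a
candidate survives only if detected in the anterior primitive streak and in
none of the caudal/anterior neural domains, the caudal streak or the
non-neural ectoderm.  Detection in the anterior midline (which contains
organizer derivatives) is permitted and, optionally, required.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from mszscreen.simulate import DISALLOWED_REGIONS, REGIONS


def binarize_regions(regional: pd.DataFrame, delta: float = 1.0) -> pd.DataFrame:
    """Binarize a gene x region expression table into detected flags.

    A region is called detected when its value is at least ``delta``
    (closed threshold, so a value exactly at ``delta`` counts).  The proxy
    for an RT-PCR band call.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    unknown = set(regional.columns) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region name(s): {sorted(unknown)}")
    missing = set(REGIONS) - set(regional.columns)
    if missing:
        raise ValueError(f"missing region column(s): {sorted(missing)}")
    if (regional.to_numpy() < 0).any():
        raise ValueError("regional expression contains negative values")
    return (regional[list(REGIONS)] >= delta)


def regional_specificity_filter(
    presence: pd.DataFrame,
    candidates: Sequence[str],
    require_midline: bool = False,
) -> list[str]:
    """Keep candidates detected in the anterior PS and nowhere disallowed.

    ``presence`` is the boolean table from :func:`binarize_regions`.  Order
    of ``candidates`` is preserved; the output is always a subset of the
    input, and the filter is idempotent.
    """
    missing = [g for g in candidates if g not in presence.index]
    if missing:
        raise KeyError(
            f"candidate gene(s) absent from the regional table: {missing[:5]}"
        )
    sub = presence.loc[list(candidates)]
    keep = sub["anterior_PS"] & ~sub[list(DISALLOWED_REGIONS)].any(axis=1)
    if require_midline:
        keep &= sub["anterior_midline"]
    kept_flags = keep.to_numpy()
    return [g for g, ok in zip(candidates, kept_flags) if ok]
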