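"""Functional subdomain metadata for the 53-component template set."""

from __future__ import annotations

import pandas as pd

#: Ordered subdomain -> number of template components.
SUBDOMAIN_SIZES: dict[str, int] = {
    "AUD": 2,
    "CER": 4,
    "CON": 17,
    "DMN": 7,
    "SCN": 5,
    "SMN": 9,
    "VIS": 9,
}

#: Default block partition used by the synthetic covariance builder.
DEFAULT_BLOCKS: tuple[int, ...] = tuple(SUBDOMAIN_SIZES.values())

#: Total template components.
N_COMPONENTS: int = sum(SUBDOMAIN_SIZES.values())


def component_table() -> pd.DataFrame:
    """Component-metadata table mapping component id to its subdomain.

    Component ids are 0-based and assigned contiguously per subdomain in the
    order of :data:`SUBDOMAIN_SIZES`.
    """
    rows = []
    cid = 0
    for name, size in SUBDOMAIN_SIZES.items():
        for _ in range(size):
            rows.append({"component": cid, "subdomain": name})
            cid += 1
    return pd.DataFrame(rows)


def subdomain_slices() -> dict[str, slice]:
    """Contiguous component index ranges per subdomain."""
    out = {}
    start = 0
    for name, size in SUBDOMAIN_SIZES.items():
        out[name] = slice(start, start + size)
        start += size
    return out
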