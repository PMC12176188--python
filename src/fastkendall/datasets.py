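"""Packaged example datasets.

The ``arcade`` dataset pairs the number of computer-science doctorates
awarded in the United States with the total revenue generated by
arcades (billions of USD), annually for 2000-2009. It is the classic
spurious-correlation illustration: a strong monotone association with
no causal mechanism, which makes it a good worked example for a rank
correlation test (n = 10, no ties).
"""

from __future__ import annotations

import pandas as pd

from .core import PairedSample

__all__ = ["arcade", "arcade_sample", "FIXTURES"]

_ARCADE_ROWS = [
    (2000, 861, 1.196),
    (2001, 830, 1.176),
    (2002, 809, 1.269),
    (2003, 867, 1.240),
    (2004, 948, 1.307),
    (2005, 1129, 1.435),
    (2006, 1453, 1.601),
    (2007, 1656, 1.654),
    (2008, 1787, 1.803),
    (2009, 1611, 1.734),
]


def arcade() -> pd.DataFrame:
    """The doctorates-vs-arcade-revenue table as a DataFrame."""
    return pd.DataFrame(_ARCADE_ROWS, columns=["year", "doctorates", "revenue"])


def arcade_sample() -> PairedSample:
    """The arcade data as a validated (doctorates, revenue) pair."""
    df = arcade()
    return PairedSample(
        df["doctorates"].to_numpy(float), df["revenue"].to_numpy(float)
    )


FIXTURES = {"arcade": arcade_sample}
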