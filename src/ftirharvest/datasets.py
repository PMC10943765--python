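"""Bundled example data.

A small table of environmental and trait measurements for *Dendrobium
officinale* over the six harvest-window months (November-April), at the
magnitudes typical of a Yunnan planting site: solar radiation (sard,
KJ m-2 day-1), precipitation (pre, mm), and the nine plant traits X1-X9
(stem length in cm, fresh/dry stem and leaf weights in g, stem/leaf dry
matter and water content in %).  The dry-matter and water-content columns
are complements: X6 + X8 = 100 and X7 + X9 = 100 to the printed 0.1
precision — the property used by the worked examples and checks.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_harvest_window_table"]

_HARVEST_CSV = """\
month,sard,pre,X1,X2,X3,X4,X5,X6,X7,X8,X9
1,12780,13,18.26,5.86,3.55,1.08,0.56,18.53,15.7,81.47,84.3
2,15601,14,10.79,3.08,1.9,0.57,0.26,18.7,13.97,81.3,86.03
3,17831,148,23.49,4.11,3.41,0.83,0.46,20.53,14.04,79.47,85.96
4,19063,448,21.82,2.93,2.66,0.64,0.39,22.37,14.93,77.63,85.07
11,12533,11,32.69,6.98,6.16,0.99,0.76,14.27,12.5,85.73,87.5
12,11527,88,31.95,6.77,4.17,1.35,0.73,19.67,17.33,80.33,82.67
"""


def load_harvest_window_table() -> pd.DataFrame:
    """Harvest-window (months 11-4) environment and mean trait values."""
    return pd.read_csv(io.StringIO(_HARVEST_CSV))
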