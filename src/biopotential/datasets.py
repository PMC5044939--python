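"""Packaged datasets.

Two small plain-text resources ship with the package:

* the nFK reference table (see :mod:`biopotential.soil_capacity`);
* 27 years (1981-2007) of observed regional harvest statistics and crop-model
  predictions for silage maize (dt fresh mass/ha) and winter wheat (dt
  grain/ha) in the region of Hannover, including the originally printed
  per-year error and adjusted columns for cross-checking.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_hannover_yields"]


def load_hannover_yields() -> pd.DataFrame:
    """Observed/predicted maize and winter-wheat yields, Hannover 1981-2007.

    Returns a year-row DataFrame with columns ``{maize,wheat}_obs``,
    ``{maize,wheat}_pred`` plus the ``*_printed`` error/adjusted columns as
    originally reported (one decimal).  A handful of printed wheat "adjust"
    values (2000-2006) are internally inconsistent with factor x prediction;
    they are shipped verbatim.
    """
    path = resources.files("biopotential.data").joinpath("hannover_yields_1981_2007.csv")
    with path.open() as fh:
        return pd.read_csv(fh, comment="#").set_index("year")
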