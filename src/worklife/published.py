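"""Published register-based expectancy estimates for Spain, 2004-2013.

Reference values from a published multistate working-life table for Spain:
remaining life expectancy at age 15, in years, spent in each labor-force
state, by sex and two-year period (a period "t/t+1" pools calendar years t
and t+1 because it is built from year-t-to-t+1 transitions). The values are
used as worked-example inputs for arithmetic identities of the pipeline —
state components summing to the total, and the recession loss read off the
employed column — not as targets the synthetic pipeline could reproduce
(the underlying register sample is confidential).
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE = """\
sex,period,employed,unemployed,inactive,retired,total
male,2004/2005,37.8,2.4,5.8,16.5,62.5
male,2005/2006,36.5,2.2,7.7,16.1,62.2
male,2006/2007,37.5,2.6,6.5,16.6,63.1
male,2007/2008,32.1,4.0,10.8,16.4,63.0
male,2008/2009,25.6,6.7,14.6,16.7,63.6
male,2009/2010,28.5,6.4,12.2,17.0,64.0
male,2010/2011,29.3,5.6,12.3,17.3,64.4
male,2011/2012,26.1,6.2,15.1,17.2,64.5
male,2012/2013,28.8,5.9,12.6,17.4,64.6
female,2004/2005,32.8,3.0,12.3,20.9,68.5
female,2005/2006,30.5,2.7,15.3,20.5,69.0
female,2006/2007,32.6,3.6,12.3,21.0,69.3
female,2007/2008,30.0,4.1,14.6,20.8,69.5
female,2008/2009,25.6,5.4,18.1,20.5,69.6
female,2009/2010,26.6,5.9,16.6,20.9,69.6
female,2010/2011,27.2,5.3,16.8,21.1,69.7
female,2011/2012,24.9,5.4,18.7,21.3,70.3
female,2012/2013,24.7,4.8,19.6,21.3,70.3
"""

#: Pre-recession and recession periods used for the headline loss comparison.
PRE_RECESSION_PERIOD = "2006/2007"
RECESSION_PERIOD = "2008/2009"

STATE_COLUMNS = ["employed", "unemployed", "inactive", "retired"]


def spain_expectancy_table() -> pd.DataFrame:
    """The published expectancy-by-period table as a DataFrame."""
    return pd.read_csv(io.StringIO(_TABLE))


def component_sums(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each row's total as the sum of its four state components.

    Adds ``component_sum`` and ``gap`` (component sum minus printed total)
    columns — the additivity identity of the multistate life table applied
    to the printed, independently rounded values.
    """
    df = (table if table is not None else spain_expectancy_table()).copy()
    df["component_sum"] = df[STATE_COLUMNS].sum(axis=1)
    df["gap"] = df["component_sum"] - df["total"]
    return df


def recession_wle_loss(sex: str, table: pd.DataFrame | None = None) -> float:
    """Years of WLE lost between the pre-recession and recession periods.

    Read from the employed column: WLE(2006/2007) minus WLE(2008/2009).
    """
    df = table if table is not None else spain_expectancy_table()
    df = df[df["sex"] == sex].set_index("period")
    return float(df.loc[PRE_RECESSION_PERIOD, "employed"] - df.loc[RECESSION_PERIOD, "employed"])
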