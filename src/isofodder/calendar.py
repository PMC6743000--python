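"""Day-of-year conventions.

The seasonal model works on a fixed 365-day year in "Julian days" with
**day 0 = January 15th**; bimonthly diet bins are calendar two-month periods
(Jan–Feb ... Nov–Dec), so model days are shifted by the 14-day offset between
January 1st and January 15th before binning.  Leap years are ignored.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365
#: Calendar day-of-year (0-based, Jan 1 = 0) of model day 0 (Jan 15).
JAN15_CALENDAR_DAY = 14

BIMONTH_LABELS = ("Jan-Feb", "Mar-Apr", "May-Jun", "Jul-Aug", "Sep-Oct", "Nov-Dec")

# cumulative first calendar day of each two-month bin (365-day year):
# Jan1, Mar1, May1, Jul1, Sep1, Nov1, and the year end as a closing edge
BIMONTH_EDGES = np.array([0, 59, 120, 181, 243, 304, 365])


def model_day_to_calendar(day):
    """Convert model day (0 = Jan 15) to 0-based calendar day-of-year."""
    return np.mod(np.asarray(day, dtype=float) + JAN15_CALENDAR_DAY, DAYS_PER_YEAR)


def bimonth_of_model_day(day):
    """Two-month calendar bin label(s) for model day(s) (0 = Jan 15).

    Returns a single label for scalar input, else an object array of labels.
    """
    cal = model_day_to_calendar(day)
    idx = np.searchsorted(BIMONTH_EDGES, cal, side="right") - 1
    idx = np.clip(idx, 0, 5)
    labels = np.asarray(BIMONTH_LABELS, dtype=object)[idx]
    if np.isscalar(day) or np.ndim(day) == 0:
        return labels.item() if labels.ndim == 0 else labels
    return labels
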