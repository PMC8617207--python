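"""Season windows used throughout the analysis.

The growing season (GS) runs May through October and is split into an
early (May-Jun), peak (Jul-Aug) and late (Sep-Oct) portion.  All windows
are sets of calendar months; daily series are filtered by month.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SeasonWindow:
    """A named set of calendar months.

    Parameters
    ----------
    name : str
        One of ``"GS"``, ``"early"``, ``"peak"``, ``"late"`` for the
        standard windows, or any label for a custom window.
    months : frozenset of int
        Calendar months (1-12) belonging to the window.
    """

    name: str
    months: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.months:
            raise ValueError("season window needs at least one month")
        if not all(1 <= m <= 12 for m in self.months):
            raise ValueError("months must be in 1..12")

    def mask(self, dates) -> "pd.Series":  # noqa: F821
        """Boolean mask selecting days of ``dates`` inside the window."""
        import pandas as pd

        months = pd.DatetimeIndex(dates).month
        return pd.Series(
            [m in self.months for m in months], index=range(len(months))
        ).to_numpy()


GS = SeasonWindow("GS", frozenset({5, 6, 7, 8, 9, 10}))
EARLY_GS = SeasonWindow("early", frozenset({5, 6}))
PEAK_GS = SeasonWindow("peak", frozenset({7, 8}))
LATE_GS = SeasonWindow("late", frozenset({9, 10}))

SEASONS = {"GS": GS, "early": EARLY_GS, "peak": PEAK_GS, "late": LATE_GS}


def get_season(name: str) -> SeasonWindow:
    """Look up a standard season window by name (``GS|early|peak|late``)."""
    try:
        return SEASONS[name]
    except KeyError:
        raise KeyError(
            f"unknown season {name!r}; expected one of {sorted(SEASONS)}"
        ) from None
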