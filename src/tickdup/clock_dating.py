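"""Molecular-clock dating of duplication events and age binning.

Synonymous substitutions are assumed to accumulate clock-like, so the age
of a duplication follows from T = Ks / (2 r): the divergence Ks accrues at
rate r on each of the two descendant lineages over time T. Rates r are
supplied as calibrations in substitutions per synonymous site per year;
the shipped default is the Drosophila melanogaster genome-wide estimate of
1.6e-8 /site/year (16 substitutions per site per billion years, i.e.
0.016 /site/MY), the only invertebrate genome-wide calibration available.
Other calibrations can be loaded from a user TSV to produce a range of
dates per event.

Pair-level ages are binned on the fixed scheme used for duplication-age
histograms: 0.1-MY steps on [0, 6) MY, then non-linear widths 1, 4, 5, 20
and 140 MY (edges 6, 7, 11, 16, 36, 176), plus an overflow bin beyond
176 MY. Bins are left-closed, right-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RateCalibration",
    "DatedEvent",
    "DateBins",
    "DROSOPHILA_RATE",
    "date",
    "date_events",
    "bin_dates",
    "load_rates",
]

MY = 1e6  # years per million years


@dataclass(frozen=True)
class RateCalibration:
    species_label: str
    rate: float  # synonymous substitutions per site per year
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be > 0")


DROSOPHILA_RATE = RateCalibration(
    "D. melanogaster",
    1.6e-8,
    "genome-wide duplicate-gene estimate, 0.016 substitutions/site/MY",
)


@dataclass(frozen=True)
class DatedEvent:
    event_index: int  # 1 = youngest
    ks_stat: float | None  # median Ks of member pairs; None when empty
    rate: RateCalibration
    age_years: float | None
    n_members: int

    @property
    def age_my(self) -> float | None:
        return None if self.age_years is None else self.age_years / MY


def date(ks: float, rate: RateCalibration | float) -> float:
    """Age in years from T = Ks / (2 r)."""
    r = rate.rate if isinstance(rate, RateCalibration) else float(rate)
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if not r > 0:
        raise ValueError("rate must be > 0")
    return ks / (2.0 * r)


def date_events(
    event_ks: dict[int, Sequence[float]],
    rates: Sequence[RateCalibration] = (DROSOPHILA_RATE,),
) -> list[DatedEvent]:
    """One dated row per (event, calibration rate).

    ``event_ks`` maps the 1-indexed event to the Ks values of its assigned
    member pairs; the median member Ks is dated under every calibration.
    Events are ordered youngest first; an event with no members yields a
    flagged row with undefined age.
    """
    if not event_ks:
        raise ValueError("no events to date")
    rows: list[DatedEvent] = []
    for ev in sorted(event_ks):
        members = np.asarray(event_ks[ev], float)
        for rate in rates:
            if members.size == 0:
                rows.append(DatedEvent(ev, None, rate, None, 0))
            else:
                med = float(np.median(members))
                rows.append(DatedEvent(ev, med, rate, date(med, rate), members.size))
    return rows


def events_table(events: Iterable[DatedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event": e.event_index,
                "ks_median": e.ks_stat,
                "rate_label": e.rate.species_label,
                "rate_per_site_per_year": e.rate.rate,
                "age_my": e.age_my,
                "n_members": e.n_members,
            }
            for e in events
        ],
        columns=["event", "ks_median", "rate_label", "rate_per_site_per_year",
                 "age_my", "n_members"],
    )


def _bin_edges_my() -> np.ndarray:
    fine = np.round(np.arange(0, 60 + 1) * 0.1, 10)  # 0.1-MY steps to 6 MY
    coarse = np.array([7.0, 11.0, 16.0, 36.0, 176.0])
    return np.concatenate([fine, coarse])


@dataclass(frozen=True)
class DateBins:
    edges_my: np.ndarray  # bin edges in MY; final bin is overflow > last edge
    counts: np.ndarray  # one count per [edge_i, edge_{i+1}) bin, + overflow

    def table(self) -> pd.DataFrame:
        lefts = list(self.edges_my[:-1]) + [self.edges_my[-1]]
        rights = list(self.edges_my[1:]) + [np.inf]
        return pd.DataFrame(
            {"left_my": lefts, "right_my": rights, "count": self.counts}
        )


def bin_dates(ages_years: Sequence[float]) -> DateBins:
    """Histogram of pair ages on the fixed duplication-age bin scheme.

    Left-closed right-open bins; counts (including overflow) sum to the
    number of input ages.
    """
    ages = np.asarray(ages_years, float) / MY
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    edges = _bin_edges_my()
    idx = np.searchsorted(edges, ages, side="right") - 1
    counts = np.zeros(edges.size, dtype=int)  # edges.size-1 bins + overflow
    for i in idx:
        counts[min(max(i, 0), edges.size - 1)] += 1
    return DateBins(edges, counts)


def load_rates(path: str | Path) -> list[RateCalibration]:
    """Rate table TSV with columns species_label, rate_per_site_per_year,
    note (optional)."""
    df = pd.read_csv(path, sep="\t")
    return [
        RateCalibration(
            str(r["species_label"]),
            float(r["rate_per_site_per_year"]),
            str(r.get("note", "")),
        )
        for _, r in df.iterrows()
    ]
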