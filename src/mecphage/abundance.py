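"""Per-species relative abundances and electrode-affiliation calls.

A species is called electrode-affiliated when its mean relative abundance on
an electrode exceeds 0.1% and both its mean and maximum abundance there
strictly exceed the mean and maximum over the non-electrode comparison group
(tubing, suspension and inoculum samples). A species passing for both
electrodes is assigned the one with the larger mean (tie: anode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mecphage.errors import EmptySampleError, InsufficientSamplesError

ELECTRODES = ("anode", "cathode")
NON_ELECTRODE = ("tubing", "suspension", "inoculum")  # foam deliberately excluded


@dataclass
class AbundanceTable:
    """Species-by-sample relative abundances in percent.

    ``values`` rows are species, columns samples; ``unassigned`` holds the
    percentage of counts per sample not attributed to any species, so column
    sums of ``values`` plus the remainder equal 100.
    """

    values: pd.DataFrame
    unassigned: pd.Series
    sample_locations: dict[str, str] = field(default_factory=dict)
    sample_mecs: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class AffiliationCall:
    species_id: str
    call: str  # anode | cathode | none
    mean_anode: float
    max_anode: float
    mean_cathode: float
    max_cathode: float
    mean_other: float
    max_other: float


def species_abundance(
    read_counts: pd.DataFrame,
    contig_to_species: Mapping[str, str],
    sample_locations: Mapping[str, str] | None = None,
    sample_mecs: Mapping[str, str] | None = None,
) -> AbundanceTable:
    """Aggregate contig read counts to species-level percentages.

    abundance(species, sample) = 100 * sum(counts of member contigs) /
    total counts in sample. Contigs not mapped to a species contribute to the
    unassigned remainder. Raises ``EmptySampleError`` on all-zero columns.
    """
    totals = read_counts.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise EmptySampleError(f"samples with zero total counts: {list(empty.index)}")
    species = read_counts.index.to_series().map(lambda c: contig_to_species.get(c))
    assigned = read_counts[species.notna()].groupby(species.dropna()).sum()
    values = 100.0 * assigned / totals
    values = values.sort_index()
    values.index.name = "species_id"
    unassigned = 100.0 - values.sum(axis=0)
    return AbundanceTable(
        values=values,
        unassigned=unassigned.clip(lower=0.0),
        sample_locations=dict(sample_locations or {}),
        sample_mecs=dict(sample_mecs or {}),
    )


def classify_affiliation(
    table: AbundanceTable,
    min_mean: float = 0.1,
) -> list[AffiliationCall]:
    """Apply the electrode-affiliation rule to every species.

    Requires at least one anode, one cathode and one non-electrode sample.
    All comparisons are strict; the non-electrode group excludes the opposite
    electrode and foam samples.
    """
    loc = table.sample_locations
    anode = [s for s in table.samples if loc.get(s) == "anode"]
    cathode = [s for s in table.samples if loc.get(s) == "cathode"]
    other = [s for s in table.samples if loc.get(s) in NON_ELECTRODE]
    if not anode or not cathode or not other:
        raise InsufficientSamplesError(
            "need >=1 anode, >=1 cathode and >=1 non-electrode sample"
        )

    calls = []
    for sp in table.species:
        row = table.values.loc[sp]
        stats = {
            "anode": (row[anode].mean(), row[anode].max()),
            "cathode": (row[cathode].mean(), row[cathode].max()),
        }
        mean_o, max_o = row[other].mean(), row[other].max()
        passing = [
            e
            for e in ELECTRODES
            if stats[e][0] > min_mean and stats[e][0] > mean_o and stats[e][1] > max_o
        ]
        if not passing:
            call = "none"
        elif len(passing) == 1:
            call = passing[0]
        else:  # larger mean wins; tie -> anode
            call = "cathode" if stats["cathode"][0] > stats["anode"][0] else "anode"
        calls.append(
            AffiliationCall(
                species_id=sp,
                call=call,
                mean_anode=float(stats["anode"][0]),
                max_anode=float(stats["anode"][1]),
                mean_cathode=float(stats["cathode"][0]),
                max_cathode=float(stats["cathode"][1]),
                mean_other=float(mean_o),
                max_other=float(max_o),
            )
        )
    return calls


def affiliation_frame(calls: Sequence[AffiliationCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
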