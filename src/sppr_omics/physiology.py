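"""Chemostat physiology: specific rates and yields at steady state.

At steady state in a substrate-limited chemostat the dilution rate ``D``
equals the specific growth rate. With biomass dry weight ``X`` (g/L),
extracellular protein ``P`` (g/L) and substrate concentrations in the feed
(``S_feed``) and residual in the vessel (``S_res``), the standard balances
give

* SPPR  = D * P / X          (specific extracellular protein production
  rate, reported in mg protein per g biomass per hour, i.e. the g/g/h
  balance scaled by 1000),
* q_s   = D * (S_feed - S_res) / X   (specific substrate consumption rate),
* Y_xs  = X / (S_feed - S_res)       (biomass yield on substrate),
* Y_ps  = P / (S_feed - S_res)       (protein yield on substrate).

Residual substrate below the detection limit is entered as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

CONDITIONS = ("D03", "D06", "HD")


class PhysiologyError(ValueError):
    """Invalid cultivation record or contrast request."""


@dataclass
class CultivationRecord:
    """One chemostat sample's measurements and derived specific rates.

    Units: dilution_rate h^-1; biomass, protein, substrate_feed,
    substrate_residual g/L; sppr mg protein * g biomass^-1 * h^-1;
    qs g substrate * g biomass^-1 * h^-1; yields g/g.
    """

    sample_id: str
    condition: str
    dilution_rate: float
    biomass: float
    protein: float
    substrate_feed: float
    substrate_residual: float = 0.0
    sppr: float | None = None
    qs: float | None = None
    yield_xs: float | None = None
    yield_ps: float | None = None

    def validate(self) -> None:
        if self.dilution_rate <= 0:
            raise PhysiologyError(f"{self.sample_id}: dilution rate must be > 0")
        if self.biomass <= 0:
            raise PhysiologyError(f"{self.sample_id}: biomass must be > 0")
        if self.substrate_residual > self.substrate_feed:
            raise PhysiologyError(
                f"{self.sample_id}: residual substrate exceeds feed substrate"
            )
        if self.protein < 0 or self.substrate_residual < 0:
            raise PhysiologyError(f"{self.sample_id}: negative concentration")


def compute_rates(record: CultivationRecord) -> CultivationRecord:
    """Return a copy of *record* with SPPR, q_s, Y_xs and Y_ps filled in.

    Raises :class:`PhysiologyError` (naming the sample) if the record is
    invalid or the substrate consumption is zero, which would make yields
    undefined.
    """
    record.validate()
    consumed = record.substrate_feed - record.substrate_residual
    if consumed <= 0:
        raise PhysiologyError(
            f"{record.sample_id}: no substrate consumed (feed == residual)"
        )
    sppr = 1000.0 * record.dilution_rate * record.protein / record.biomass
    qs = record.dilution_rate * consumed / record.biomass
    return replace(
        record,
        sppr=sppr,
        qs=qs,
        yield_xs=record.biomass / consumed,
        yield_ps=record.protein / consumed,
    )


def compute_rates_all(records: Iterable[CultivationRecord]) -> list[CultivationRecord]:
    return [compute_rates(r) for r in records]


@dataclass
class ContrastResult:
    field: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    difference: float
    t: float
    p: float


def condition_contrast(
    records: Sequence[CultivationRecord],
    field: str,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> ContrastResult:
    """Two-sample t-test of a derived field between two conditions.

    Pooled-variance Student's t by default; ``welch=True`` switches to the
    Welch unequal-variance form. The difference reported is
    mean(group_a) - mean(group_b).
    """
    a = np.array(
        [getattr(r, field) for r in records if r.condition == group_a], dtype=float
    )
    b = np.array(
        [getattr(r, field) for r in records if r.condition == group_b], dtype=float
    )
    if len(a) < 2 or len(b) < 2:
        raise PhysiologyError(
            f"need >=2 records per group for contrast {group_a} vs {group_b} "
            f"(got {len(a)}, {len(b)})"
        )
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise PhysiologyError(f"field {field!r} not computed for all records")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return ContrastResult(
        field=field,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t=float(t),
        p=float(p),
    )
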