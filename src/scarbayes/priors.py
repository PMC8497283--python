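"""Prior elicitation from historical trial counts.

Historical two-arm trials with binary outcomes are turned into per-arm Beta
prior distributions by treating observed events as pseudo-counts: an arm
with ``e`` events out of ``n`` contributes ``e`` to the Beta ``alpha`` shape
and ``n - e`` to ``beta``.  Borrowing strength is controlled by a power-prior
style discount weight in [0, 1] multiplying the historical pseudo-counts,
with a configurable base prior acting as the initial prior.

Three named scenarios are supported:

``informative``
    weight 1 — historical counts enter at face value.
``low_informative``
    weight 0.5 — historical information is discounted by 50%.
``uninformative``
    weight 0 — no borrowing; the prior is the base alone (flat Beta(1, 1)
    by default, Jeffreys Beta(0.5, 0.5) selectable).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ArmCounts",
    "HistoricalTrial",
    "BetaParams",
    "ArmPriors",
    "PriorScenario",
    "SCENARIO_WEIGHTS",
    "beta_from_counts",
    "reconstruct_events",
    "pool_historical",
    "make_scenario",
    "load_historical_trials",
]


@dataclass(frozen=True)
class ArmCounts:
    """Binomial sufficient statistic for one trial arm.

    Parameters
    ----------
    events : int
        Number of subjects with the outcome event (kidney scar).
    n : int
        Number of evaluable subjects in the arm.
    """

    events: int
    n: int

    def __post_init__(self) -> None:
        if int(self.events) != self.events or int(self.n) != self.n:
            raise ValueError("events and n must be integers")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 <= self.events <= self.n:
            raise ValueError(
                f"events must satisfy 0 <= events <= n, got {self.events}/{self.n}"
            )

    @property
    def nonevents(self) -> int:
        return self.n - self.events

    @property
    def proportion(self) -> float:
        return self.events / self.n


@dataclass(frozen=True)
class HistoricalTrial:
    """One historical two-arm trial used as a prior data source."""

    label: str
    treat: ArmCounts
    control: ArmCounts


@dataclass(frozen=True)
class BetaParams:
    """Shape pair of a Beta distribution; both shapes strictly positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta shapes must be strictly positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


@dataclass(frozen=True)
class ArmPriors:
    """Pair of per-arm Beta priors entering the beta-binomial model."""

    treat: BetaParams
    control: BetaParams


SCENARIO_WEIGHTS = {"informative": 1.0, "low_informative": 0.5, "uninformative": 0.0}

#: Base prior used for pure historical pooling: contributes nothing, so the
#: prior shape equals the (possibly discounted) historical pseudo-counts.
ZERO_BASE: tuple[float, float] = (0.0, 0.0)

#: Default base for the uninformative scenario: flat over the proportion.
FLAT_BASE: tuple[float, float] = (1.0, 1.0)

#: Jeffreys alternative for the uninformative scenario.
JEFFREYS_BASE: tuple[float, float] = (0.5, 0.5)


def _base_tuple(base: BetaParams | Sequence[float] | None) -> tuple[float, float]:
    """Normalize a base prior to a (alpha, beta) pair; (0, 0) is allowed here."""
    if base is None:
        return ZERO_BASE
    if isinstance(base, BetaParams):
        return base.as_tuple()
    a, b = float(base[0]), float(base[1])
    if a < 0 or b < 0:
        raise ValueError(f"base prior shapes must be >= 0, got ({a}, {b})")
    return (a, b)


def beta_from_counts(
    counts: ArmCounts, base: BetaParams | Sequence[float] | None = None
) -> BetaParams:
    """Beta prior from one arm's counts: alpha = base + events, beta = base + non-events.

    The convention is pseudo-count addition *without* an implicit +1, so
    6/18 with a zero base yields Beta(6, 12).  A zero base combined with
    zero events (or zero non-events) would produce a degenerate shape;
    this raises with instructions to supply a positive base.
    """
    a0, b0 = _base_tuple(base)
    alpha = a0 + counts.events
    beta = b0 + counts.nonevents
    if alpha <= 0 or beta <= 0:
        raise ValueError(
            f"degenerate Beta({alpha}, {beta}) from counts {counts.events}/{counts.n}: "
            "supply a base prior with positive shapes (e.g. base=(1, 1))"
        )
    return BetaParams(alpha, beta)


def reconstruct_events(percent: float, n: int) -> int:
    """Reconstruct an integer event count from a printed percentage.

    Uses round-half-to-even on ``percent/100 * n``, clipped to [0, n].
    Needed for historical reports that print only percentages (e.g. scar
    rates of 9.8% vs 16.8% among completers).
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    k = int(round(percent / 100.0 * n))  # Python round is half-to-even
    return min(max(k, 0), n)


def pool_historical(
    trials: Iterable[HistoricalTrial],
    weight: float,
    base: BetaParams | Sequence[float] | None = None,
) -> ArmPriors:
    """Pool historical counts into per-arm Beta priors with power-prior discounting.

    Per arm: ``alpha = base_a + weight * sum(events)`` and
    ``beta = base_b + weight * sum(non-events)``.  Pooling is additive, so
    it is invariant to trial order and to splitting a trial into sub-trials
    with the same totals.  Discounted pseudo-counts are carried as reals.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    a0, b0 = _base_tuple(base)
    at, bt = a0, b0
    ac, bc = a0, b0
    for trial in trials:
        at += weight * trial.treat.events
        bt += weight * trial.treat.nonevents
        ac += weight * trial.control.events
        bc += weight * trial.control.nonevents
    if min(at, bt, ac, bc) <= 0:
        raise ValueError(
            "degenerate pooled prior (a zero shape): supply a base prior with "
            "positive shapes (e.g. base=(1, 1))"
        )
    return ArmPriors(treat=BetaParams(at, bt), control=BetaParams(ac, bc))


@dataclass(frozen=True)
class PriorScenario:
    """Named borrowing scenario: discount weight plus base prior.

    The ``weight`` is fixed by ``name`` (1, 0.5 and 0 for informative,
    low_informative and uninformative).  ``base`` is the initial prior added
    before the weighted historical counts; the uninformative scenario
    returns the base exactly.
    """

    name: str
    base: tuple[float, float] = field(default=ZERO_BASE)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_WEIGHTS:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of "
                f"{sorted(SCENARIO_WEIGHTS)}"
            )
        object.__setattr__(self, "base", _base_tuple(self.base))

    @property
    def weight(self) -> float:
        return SCENARIO_WEIGHTS[self.name]

    def build(self, trials: Sequence[HistoricalTrial]) -> ArmPriors:
        return make_scenario(self.name, trials, base=self.base)

    @classmethod
    def informative(cls) -> "PriorScenario":
        return cls("informative", base=ZERO_BASE)

    @classmethod
    def low_informative(cls) -> "PriorScenario":
        return cls("low_informative", base=ZERO_BASE)

    @classmethod
    def uninformative(cls, base: Sequence[float] = FLAT_BASE) -> "PriorScenario":
        return cls("uninformative", base=tuple(base))


def make_scenario(
    name: str,
    trials: Sequence[HistoricalTrial],
    base: BetaParams | Sequence[float] | None = None,
) -> ArmPriors:
    """Build per-arm priors for a named scenario.

    ``informative`` pools at weight 1, ``low_informative`` at weight 0.5;
    ``uninformative`` ignores the historical trials and returns the base
    prior per arm (flat Beta(1, 1) when no base is given).
    """
    if name not in SCENARIO_WEIGHTS:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_WEIGHTS)}"
        )
    if name == "uninformative":
        a0, b0 = _base_tuple(base if base is not None else FLAT_BASE)
        prior = BetaParams(a0, b0)
        return ArmPriors(treat=prior, control=prior)
    return pool_historical(trials, SCENARIO_WEIGHTS[name], base=base)


# ---------------------------------------------------------------------------
# Config / file input


def _trial_from_mapping(entry: dict, where: str) -> HistoricalTrial:
    try:
        return HistoricalTrial(
            label=str(entry["label"]),
            treat=ArmCounts(int(entry["treat"]["events"]), int(entry["treat"]["n"])),
            control=ArmCounts(
                int(entry["control"]["events"]), int(entry["control"]["n"])
            ),
        )
    except KeyError as exc:
        raise ValueError(f"{where}: missing field {exc.args[0]!r}") from exc


def load_historical_trials(path: str | Path) -> list[HistoricalTrial]:
    """Read historical trials from JSON/YAML ``{trials: [...]}`` or a CSV.

    The CSV dialect has a header ``label,arm,events,n`` with one row per
    arm and ``arm`` in {treat, control}; both arms must be present for
    every label.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _trials_from_csv(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.suffix.lower() in {".yaml", ".yml"} else json.load(fh)
    entries = doc["trials"] if isinstance(doc, dict) else doc
    return [
        _trial_from_mapping(e, f"{path}: trials[{i}]") for i, e in enumerate(entries)
    ]


def _trials_from_csv(path: Path) -> list[HistoricalTrial]:
    arms: dict[str, dict[str, ArmCounts]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            label, arm = row["label"], row["arm"]
            if arm not in {"treat", "control"}:
                raise ValueError(f"{path}: row {i}: arm must be treat|control, got {arm!r}")
            if label not in arms:
                arms[label] = {}
                order.append(label)
            arms[label][arm] = ArmCounts(int(row["events"]), int(row["n"]))
    trials = []
    for label in order:
        if set(arms[label]) != {"treat", "control"}:
            raise ValueError(f"{path}: trial {label!r} is missing an arm")
        trials.append(
            HistoricalTrial(label=label, treat=arms[label]["treat"], control=arms[label]["control"])
        )
    return trials
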