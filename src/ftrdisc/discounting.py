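"""Hyperbolic discount-rate (k) estimation from binary intertemporal choices.

A participant repeatedly chooses between a smaller-sooner reward (SSR,
available now) and a larger-later reward (LLR, available after a delay D).
Under hyperbolic discounting the present value of the LLR is

    V = A / (1 + k * D)

with A the delayed amount and k a per-week discount rate.  Each battery item
defines one indifference rate k* = (LLR/SSR - 1) / D at which V(LLR) = SSR.
The fitting procedure enumerates every item's indifference rate as a
candidate k, predicts the full choice vector for each candidate (SSR chosen
iff SSR strictly exceeds the discounted LLR), and retains the candidate(s)
with the highest match proportion against the observed choices; ties are
resolved by the geometric mean of the tied candidates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SSR = "SSR"
LLR = "LLR"

# Delay-unit convention: everything in weeks, calendar month = 365.25/12 days.
WEEKS_PER_DAY = 1.0 / 7.0
WEEKS_PER_MONTH = 365.25 / 12.0 / 7.0
WEEKS_PER_YEAR = 365.25 / 7.0

_UNIT_WEEKS = {
    "day": WEEKS_PER_DAY,
    "days": WEEKS_PER_DAY,
    "week": 1.0,
    "weeks": 1.0,
    "month": WEEKS_PER_MONTH,
    "months": WEEKS_PER_MONTH,
    "year": WEEKS_PER_YEAR,
    "years": WEEKS_PER_YEAR,
}

_NUMBER_WORDS = {
    "one": 1.0, "two": 2.0, "three": 3.0, "four": 4.0, "five": 5.0,
    "six": 6.0, "seven": 7.0, "eight": 8.0, "nine": 9.0, "ten": 10.0,
    "eleven": 11.0, "twelve": 12.0,
}

_LABEL_RE = re.compile(r"^\s*(?P<qty>.+?)\s*(?P<unit>days?|weeks?|months?|years?)\s*$")


def delay_in_weeks(label: str) -> float:
    """Convert a verbal delay label (e.g. ``"two weeks"``, ``"4½ months"``) to weeks."""
    m = _LABEL_RE.match(label.lower())
    if m is None:
        raise ValueError(f"unknown delay label: {label!r}")
    qty_str = m.group("qty").strip()
    if qty_str in _NUMBER_WORDS:
        qty = _NUMBER_WORDS[qty_str]
    else:
        half = 0.0
        if qty_str.endswith("½"):
            half = 0.5
            qty_str = qty_str[:-1].strip()
        try:
            qty = (float(qty_str) if qty_str else 0.0) + half
        except ValueError:
            raise ValueError(f"unknown delay label: {label!r}") from None
    if qty <= 0:
        raise ValueError(f"unknown delay label: {label!r}")
    return qty * _UNIT_WEEKS[m.group("unit")]


@dataclass(frozen=True)
class ChoiceItem:
    """One binary intertemporal-choice item: SSR now vs LLR after a delay."""

    item_id: str
    ssr_amount: float
    llr_amount: float
    delay_label: str
    delay_weeks: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.delay_weeks is None:
            object.__setattr__(self, "delay_weeks", delay_in_weeks(self.delay_label))
        if not self.ssr_amount > 0 or not self.llr_amount > 0:
            raise ValueError(f"item {self.item_id}: amounts must be positive")
        if not self.ssr_amount < self.llr_amount:
            raise ValueError(f"item {self.item_id}: SSR must be below LLR")
        if not self.delay_weeks > 0:
            raise ValueError(f"item {self.item_id}: delay must be positive")


@dataclass(frozen=True)
class ChoiceObservation:
    """One observed pick on a battery item."""

    participant_id: str
    item_id: str
    choice: str

    def __post_init__(self):
        if self.choice not in (SSR, LLR):
            raise ValueError(
                f"choice must be {SSR!r} or {LLR!r}, got {self.choice!r}"
            )


@dataclass(frozen=True)
class DiscountFit:
    """Best-fitting per-week discount rate for one participant."""

    participant_id: str
    k: float
    log_k: float
    match_proportion: float
    n_tied: int
    n_choices: int


def study1_battery(llr_amount: float = 10.0) -> list[ChoiceItem]:
    """SSR 4.00–9.50 by 0.50 crossed with 7 delays (one day … two years): 84 items."""
    amounts = [round(4.0 + 0.5 * i, 2) for i in range(12)]
    delays = ["one day", "two days", "one week", "two weeks",
              "one month", "six months", "two years"]
    return _crossed_battery(amounts, delays, llr_amount)


def study2_battery(llr_amount: float = 10.0) -> list[ChoiceItem]:
    """SSR 7.50–9.25 by 0.25 crossed with 8 delays (2 weeks … 4½ months): 64 items."""
    amounts = [round(7.5 + 0.25 * i, 2) for i in range(8)]
    delays = ["two weeks", "1 month", "1½ months", "2 months",
              "2½ months", "3 months", "4 months", "4½ months"]
    return _crossed_battery(amounts, delays, llr_amount)


def _crossed_battery(amounts, delays, llr_amount):
    items = []
    for d in delays:
        for a in amounts:
            items.append(ChoiceItem(
                item_id=f"ssr{a:.2f}_{d.replace(' ', '-')}",
                ssr_amount=a, llr_amount=llr_amount, delay_label=d,
            ))
    return items


def get_battery(name: str) -> list[ChoiceItem]:
    try:
        return {"study1": study1_battery, "study2": study2_battery}[name]()
    except KeyError:
        raise ValueError(f"unknown battery: {name!r}") from None


def hyperbolic_value(amount: float, k: float, delay_weeks: float) -> float:
    """Present value A / (1 + kD) of an amount delayed by D weeks."""
    if amount < 0 or k < 0 or delay_weeks < 0:
        raise ValueError("amount, k and delay must be nonnegative")
    return amount / (1.0 + k * delay_weeks)


def indifference_k(ssr: float, llr: float, delay_weeks: float) -> float:
    """The k at which the discounted LLR exactly equals the SSR."""
    if not 0 < ssr <= llr:
        raise ValueError("require 0 < ssr <= llr")
    if delay_weeks <= 0:
        raise ValueError("delay must be positive")
    return (llr / ssr - 1.0) / delay_weeks


def candidate_ks(battery: Sequence[ChoiceItem], tol: float = 1e-12) -> np.ndarray:
    """All item indifference rates, de-duplicated within ``tol``, ascending."""
    if not battery:
        raise ValueError("battery is empty")
    ks = np.sort([indifference_k(it.ssr_amount, it.llr_amount, it.delay_weeks)
                  for it in battery])
    keep = [ks[0]]
    for k in ks[1:]:
        if k - keep[-1] > tol:
            keep.append(k)
    return np.asarray(keep)


def predict_choice(item: ChoiceItem, k: float) -> str:
    """Predicted pick under rate k: SSR iff it strictly beats the discounted LLR."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return SSR if item.ssr_amount > hyperbolic_value(item.llr_amount, k, item.delay_weeks) else LLR


def _prediction_matrix(battery: Sequence[ChoiceItem], ks: np.ndarray) -> np.ndarray:
    """Boolean (n_candidates, n_items): True where the prediction is SSR."""
    ssr = np.array([it.ssr_amount for it in battery])
    llr = np.array([it.llr_amount for it in battery])
    d = np.array([it.delay_weeks for it in battery])
    return ssr[None, :] > llr[None, :] / (1.0 + ks[:, None] * d[None, :])


def fit_k(observations: Sequence[ChoiceObservation],
          battery: Sequence[ChoiceItem]) -> DiscountFit:
    """Enumerate candidate ks and retain the best-matching one (geometric-mean ties)."""
    if not observations:
        raise ValueError("no observations")
    index = {it.item_id: i for i, it in enumerate(battery)}
    seen = set()
    pid = observations[0].participant_id
    cols, ssr_chosen = [], []
    for obs in observations:
        key = (obs.participant_id, obs.item_id)
        if key in seen:
            raise ValueError(f"duplicate observation for {key}")
        seen.add(key)
        if obs.item_id not in index:
            raise ValueError(f"item {obs.item_id!r} not in battery")
        cols.append(index[obs.item_id])
        ssr_chosen.append(obs.choice == SSR)
    ks = candidate_ks(battery)
    pred = _prediction_matrix(battery, ks)[:, cols]
    matches = (pred == np.asarray(ssr_chosen)[None, :]).sum(axis=1)
    best = matches.max()
    tied = ks[matches == best]
    k = float(tied[0]) if tied.size == 1 else float(math.exp(np.mean(np.log(tied))))
    return DiscountFit(
        participant_id=pid,
        k=k,
        log_k=math.log(k),
        match_proportion=best / len(cols),
        n_tied=int(tied.size),
        n_choices=len(cols),
    )


def cohort_fit(observations: Iterable[ChoiceObservation],
               battery: Sequence[ChoiceItem]) -> tuple[pd.DataFrame, float]:
    """Fit every participant; return the fit table and the pooled match proportion."""
    by_pid: dict[str, list[ChoiceObservation]] = {}
    for obs in observations:
        by_pid.setdefault(obs.participant_id, []).append(obs)
    if not by_pid:
        raise ValueError("no observations")
    rows, matched, total = [], 0.0, 0
    for pid, obs_list in by_pid.items():
        try:
            fit = fit_k(obs_list, battery)
        except ValueError as err:
            raise ValueError(f"participant {pid}: {err}") from err
        rows.append(fit.__dict__)
        matched += fit.match_proportion * fit.n_choices
        total += fit.n_choices
    return pd.DataFrame(rows), matched / total


def battery_to_frame(battery: Sequence[ChoiceItem]) -> pd.DataFrame:
    return pd.DataFrame([it.__dict__ for it in battery])


def read_battery(path) -> list[ChoiceItem]:
    """Read a battery from delimited text (item_id, ssr_amount, llr_amount, delay_label)."""
    df = pd.read_csv(path)
    return [ChoiceItem(item_id=str(r.item_id), ssr_amount=float(r.ssr_amount),
                       llr_amount=float(r.llr_amount), delay_label=str(r.delay_label))
            for r in df.itertuples()]


def read_choice_observations(path) -> list[ChoiceObservation]:
    """Read observations from delimited text (participant_id, item_id, choice)."""
    df = pd.read_csv(path)
    return [ChoiceObservation(str(r.participant_id), str(r.item_id), str(r.choice))
            for r in df.itertuples()]
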