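"""Deterministic closed-vocabulary coding of elicited future-time-reference text.

Each elicitation item asks a participant to render a target sentence about a
future event; the free-text answer is coded into two mutually exclusive
binary classes:

* future tense — the answer contains a future auxiliary (English *will*,
  *shall*, *going to*, *about to*; Dutch *zullen*, *gaan*, *staan op het
  punt*) and no modal marker;
* present tense — the answer conjugates the item's target verb in one of its
  present-tense forms, is not future, and carries no modal marker.

Any modal marker (high- or low-certainty: *might*, *possibly*, *definitely*,
*misschien*, *zeker*, ...) suppresses both classes ("modal dominance"),
because the modal — not the tense — then carries the certainty semantics.
Vocabulary ships as editable per-language lexicon files; there is no learned
state, so coding is exactly reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

ENGLISH = "english"
DUTCH = "dutch"

_TOKEN_RE = re.compile(r"[a-z0-9À-ɏ]+")
_PAREN_RE = re.compile(r"\([^()]*\)")

DISTANCE_CATEGORIES = (
    "later today", "tomorrow", "one week", "six months", "one year",
    "two years", "ten years", "25+ years", "indeterminate", "ongoing",
)
MODALITY_CONDITIONS = ("high-certainty", "low-certainty", "neutral")
FTR_MODES = ("prediction", "intention")


@dataclass(frozen=True)
class Lexicon:
    """Closed vocabulary for one language."""

    language: str
    future_markers: tuple[tuple[str, ...], ...]
    modal_markers: tuple[tuple[str, ...], ...]
    contraction_map: Mapping[str, str] = field(default_factory=dict)
    adverbial_markers: tuple[tuple[str, ...], ...] = ()
    adverbials_count_as_future: bool = False

    def __post_init__(self):
        overlap = set(self.future_markers) & set(self.modal_markers)
        if overlap:
            raise ValueError(f"markers in both future and modal sections: {overlap}")


def _parse_marker(line: str) -> tuple[str, ...]:
    return tuple(line.lower().split())


def load_lexicon_text(language: str, text: str) -> Lexicon:
    """Parse a sectioned lexicon file ([future] / [modal] / [adverbial] / [contractions])."""
    sections: dict[str, list[str]] = {"future": [], "modal": [], "adverbial": [], "contractions": []}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].lower()
            if current not in sections:
                raise ValueError(f"unknown lexicon section [{current}]")
            continue
        if current is None:
            raise ValueError("lexicon entry before any section header")
        sections[current].append(line)
    contractions = {}
    for entry in sections["contractions"]:
        surface, _, expansion = entry.partition("=>")
        if not expansion:
            raise ValueError(f"malformed contraction entry: {entry!r}")
        contractions[surface.strip().lower()] = expansion.strip().lower()
    return Lexicon(
        language=language,
        future_markers=tuple(_parse_marker(e) for e in sections["future"]),
        modal_markers=tuple(_parse_marker(e) for e in sections["modal"]),
        contraction_map=contractions,
        adverbial_markers=tuple(_parse_marker(e) for e in sections["adverbial"]),
    )


def load_lexicon(language: str) -> Lexicon:
    """Load the packaged lexicon for ``english`` or ``dutch``."""
    ref = resources.files("ftrdisc.lexicons").joinpath(f"{language}.txt")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ValueError(f"no packaged lexicon for language {language!r}") from None
    return load_lexicon_text(language, text)


@dataclass(frozen=True)
class ElicitationItem:
    """One elicitation prompt with its target verb and design factors."""

    item_id: str
    language: str
    context_text: str
    target_template: str
    target_verb_lemma: str
    present_forms: frozenset[str]
    distance_category: str = "indeterminate"
    modality_condition: str = "neutral"
    ftr_mode: str = "prediction"
    excluded: bool = False

    def __post_init__(self):
        if not self.excluded and not self.present_forms:
            raise ValueError(f"item {self.item_id}: present_forms must be nonempty")
        if self.distance_category not in DISTANCE_CATEGORIES:
            raise ValueError(f"item {self.item_id}: bad distance {self.distance_category!r}")
        if self.modality_condition not in MODALITY_CONDITIONS:
            raise ValueError(f"item {self.item_id}: bad modality {self.modality_condition!r}")
        if self.ftr_mode not in FTR_MODES:
            raise ValueError(f"item {self.item_id}: bad mode {self.ftr_mode!r}")


@dataclass(frozen=True)
class ElicitationResponse:
    participant_id: str
    item_id: str
    text: str

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError("response text is empty")


@dataclass(frozen=True)
class FTRScore:
    """Binary future/present coding; mutually exclusive, both may be 0."""

    future: int
    present: int

    def __post_init__(self):
        if self.future not in (0, 1) or self.present not in (0, 1):
            raise ValueError("scores must be 0/1")
        if self.future + self.present > 1:
            raise ValueError("future and present classes are mutually exclusive")


@dataclass(frozen=True)
class ParticipantFTR:
    participant_id: str
    fut_proportion: float
    pres_proportion: float
    n_scored: int


def normalize(text: str, contraction_map: Mapping[str, str] | None = None) -> list[str]:
    """Lowercase, drop parentheticals, expand contractions, tokenize.

    Parenthetical material is removed before tokenization: participants were
    instructed to omit it, so echoed certainty cues are never scored.
    """
    s = text.lower()
    while _PAREN_RE.search(s):
        s = _PAREN_RE.sub(" ", s)
    if contraction_map:
        for surface in sorted(contraction_map, key=len, reverse=True):
            s = s.replace(surface, " " + contraction_map[surface] + " ")
    return _TOKEN_RE.findall(s)


def contains_marker(tokens: Sequence[str],
                    markers: Iterable[tuple[str, ...]]) -> bool:
    """True iff any marker token sequence occurs contiguously in ``tokens``."""
    n = len(tokens)
    for marker in markers:
        m = len(marker)
        if m == 0 or m > n:
            continue
        if m == 1:
            if marker[0] in tokens:
                return True
        else:
            for i in range(n - m + 1):
                if tuple(tokens[i:i + m]) == marker:
                    return True
    return False


def classify_response(response: ElicitationResponse, item: ElicitationItem,
                      lexicon: Lexicon) -> FTRScore:
    """Code one response under the future / present / modal-dominance schema."""
    if item.excluded:
        raise ValueError(f"item {item.item_id} is excluded from scoring")
    if item.language != lexicon.language:
        raise ValueError(
            f"lexicon language {lexicon.language!r} does not match item "
            f"language {item.language!r}"
        )
    tokens = normalize(response.text, lexicon.contraction_map)
    if contains_marker(tokens, lexicon.modal_markers):
        return FTRScore(0, 0)
    future = contains_marker(tokens, lexicon.future_markers)
    if not future and lexicon.adverbials_count_as_future:
        future = contains_marker(tokens, lexicon.adverbial_markers)
    if future:
        return FTRScore(1, 0)
    present = contains_marker(tokens, [(f,) for f in item.present_forms])
    return FTRScore(0, 1 if present else 0)


def score_participants(responses: Sequence[ElicitationResponse],
                       items: Sequence[ElicitationItem],
                       lexicon: Lexicon) -> list[ParticipantFTR]:
    """Per-participant future/present proportions over non-excluded items.

    Participants whose every response falls on excluded items are omitted
    (missing), never reported as zero.
    """
    item_by_id = {it.item_id: it for it in items}
    seen: set[tuple[str, str]] = set()
    agg: dict[str, list[FTRScore]] = {}
    order: list[str] = []
    for resp in responses:
        key = (resp.participant_id, resp.item_id)
        if key in seen:
            raise ValueError(f"duplicate response for {key}")
        seen.add(key)
        if resp.item_id not in item_by_id:
            raise ValueError(f"response references unknown item {resp.item_id!r}")
        item = item_by_id[resp.item_id]
        if item.excluded:
            continue
        score = classify_response(resp, item, lexicon)
        if resp.participant_id not in agg:
            order.append(resp.participant_id)
        agg.setdefault(resp.participant_id, []).append(score)
    out = []
    for pid in order:
        scores = agg[pid]
        n = len(scores)
        out.append(ParticipantFTR(
            participant_id=pid,
            fut_proportion=sum(s.future for s in scores) / n,
            pres_proportion=sum(s.present for s in scores) / n,
            n_scored=n,
        ))
    return out


def validate_against_labels(predicted: Mapping[tuple, FTRScore],
                            gold: Mapping[tuple, FTRScore]) -> dict[str, dict[str, float]]:
    """Accuracy / precision / recall per class against human-rated labels."""
    if set(predicted) != set(gold):
        raise ValueError("predicted and gold labels are not aligned on the same keys")
    keys = list(predicted)
    metrics = {}
    for cls in ("future", "present"):
        p = [getattr(predicted[k], cls) for k in keys]
        g = [getattr(gold[k], cls) for k in keys]
        tp = sum(1 for a, b in zip(p, g) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(p, g) if a == 1 and b == 0)
        fn = sum(1 for a, b in zip(p, g) if a == 0 and b == 1)
        tn = len(keys) - tp - fp - fn
        metrics[cls] = {
            "accuracy": (tp + tn) / len(keys),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        }
    return metrics
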