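"""Synthetic two-language cohorts with the structure the analysis assumes.

The generator realizes the mediation system directly: a participant's latent
standardized future-tense propensity is Normal(λ1 + α·lang, σ1) and their
latent log discount rate is Normal(λ2 + τ'·lang + β1·fut + β2·fut·lang, σ2).
The latent propensity is mapped back to a proportion through a fixed affine
back-transform (grand mean + z·grand sd, clipped to [0, 1]); intertemporal
choices follow the hyperbolic rule at the participant's latent k with an
independent symmetric flip at rate ε; elicitation text is realized from a
small per-language template grammar whose ground-truth future/present labels
are returned alongside, so the deterministic classifier can be checked
round-trip.

Default coefficients are the fitted study values; residual scales and the
back-transform are calibrated once, in closed form, against the studies'
descriptive marginals (see scripts/calibrate_generator.py) and stored below
as named constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .discounting import LLR, SSR, ChoiceItem, ChoiceObservation, get_battery, predict_choice
from .ftr import (DISTANCE_CATEGORIES, FTR_MODES, MODALITY_CONDITIONS,
                  ElicitationItem, ElicitationResponse, FTRScore, Lexicon)

logger = logging.getLogger(__name__)

# Residual scales calibrated against the descriptive marginals
# (scripts/calibrate_generator.py); back-transform solved from the
# language-wise proportion means vs the standardized-scale coefficients.
STUDY1_SIGMA1 = 0.7337
STUDY1_SIGMA2 = 1.9851
STUDY1_FUT_MEAN = 0.4543
STUDY1_FUT_SD = 0.1912
STUDY2_SIGMA1 = 0.6557
STUDY2_SIGMA2 = 1.3412
STUDY2_FUT_MEAN = 0.3937
STUDY2_FUT_SD = 0.2583


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of a synthetic cohort."""

    n_english: int
    n_dutch: int
    lambda1: float
    alpha: float
    sigma1: float
    lambda2: float
    tau_prime: float
    beta1: float
    beta2: float
    sigma2: float
    fut_mean: float
    fut_sd: float
    choice_noise: float = 0.06
    battery: str = "study1"
    n_elicitation_items: int = 26
    modal_injection_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_english < 2 or self.n_dutch < 2:
            raise ValueError("need at least 2 participants per language")
        if self.sigma1 <= 0 or self.sigma2 <= 0 or self.fut_sd <= 0:
            raise ValueError("scales must be positive")
        if not 0 <= self.choice_noise < 0.5:
            raise ValueError("choice_noise must be in [0, 0.5)")
        if not 0 <= self.modal_injection_rate <= 1:
            raise ValueError("modal_injection_rate must be in [0, 1]")


_DEFAULTS = {
    "study1": dict(
        n_english=113, n_dutch=122,
        lambda1=-0.65, alpha=1.36, sigma1=STUDY1_SIGMA1,
        lambda2=-3.00, tau_prime=0.30, beta1=0.26, beta2=-0.90, sigma2=STUDY1_SIGMA2,
        fut_mean=STUDY1_FUT_MEAN, fut_sd=STUDY1_FUT_SD,
        battery="study1", n_elicitation_items=26,
    ),
    "study2": dict(
        n_english=301, n_dutch=305,
        lambda1=-0.75, alpha=1.51, sigma1=STUDY2_SIGMA1,
        lambda2=-3.82, tau_prime=1.10, beta1=-0.07, beta2=-0.26, sigma2=STUDY2_SIGMA2,
        fut_mean=STUDY2_FUT_MEAN, fut_sd=STUDY2_FUT_SD,
        battery="study2", n_elicitation_items=24,
    ),
}


def default_params(study: str, **overrides) -> GeneratorParams:
    """Default cohort parameterization for ``study1`` or ``study2``."""
    if study not in _DEFAULTS:
        raise ValueError(f"unknown study: {study!r} (expected 'study1' or 'study2')")
    kwargs = dict(_DEFAULTS[study])
    kwargs.update(overrides)
    return GeneratorParams(**kwargs)


def gen_cohort(params: GeneratorParams) -> pd.DataFrame:
    """Draw one cohort; deterministic given ``params.seed``.

    Returns a frame with latent fut_z / log k and the back-transformed,
    clipped fut_proportion; the clip rate is logged and stored in
    ``df.attrs["clip_rate"]``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_english + params.n_dutch
    lang = np.concatenate([np.ones(params.n_english), np.zeros(params.n_dutch)])
    fut_z = rng.normal(params.lambda1 + params.alpha * lang, params.sigma1)
    mu_k = (params.lambda2 + params.tau_prime * lang
            + params.beta1 * fut_z + params.beta2 * fut_z * lang)
    log_k = rng.normal(mu_k, params.sigma2)
    raw = params.fut_mean + fut_z * params.fut_sd
    fut_prop = np.clip(raw, 0.0, 1.0)
    clip_rate = float(np.mean(raw != fut_prop))
    if clip_rate:
        logger.info("fut_proportion back-transform clipped %.2f%% of participants",
                    100 * clip_rate)
    df = pd.DataFrame({
        "participant_id": [f"p{i:04d}" for i in range(n)],
        "language": np.where(lang == 1, "english", "dutch"),
        "language_indicator": lang.astype(int),
        "fut_z_latent": fut_z,
        "fut_proportion": fut_prop,
        "log_k_latent": log_k,
        "k_latent": np.exp(log_k),
    })
    df.attrs["clip_rate"] = clip_rate
    return df


def gen_choices(participant_id: str, k_latent: float,
                battery: Sequence[ChoiceItem], choice_noise: float,
                rng: np.random.Generator) -> list[ChoiceObservation]:
    """Hyperbolic-rule choices at the latent k, each flipped with probability ε."""
    if k_latent <= 0:
        raise ValueError("k_latent must be positive")
    out = []
    flips = rng.random(len(battery)) < choice_noise
    for item, flip in zip(battery, flips):
        choice = predict_choice(item, k_latent)
        if flip:
            choice = LLR if choice == SSR else SSR
        out.append(ChoiceObservation(participant_id, item.item_id, choice))
    return out


def cohort_choices(cohort: pd.DataFrame, battery: Sequence[ChoiceItem],
                   choice_noise: float, seed: int) -> list[ChoiceObservation]:
    """Choices for every participant in a cohort (one child stream each)."""
    rng = np.random.default_rng(seed)
    out: list[ChoiceObservation] = []
    for row in cohort.itertuples():
        out.extend(gen_choices(row.participant_id, row.k_latent, battery,
                               choice_noise, rng))
    return out


# (lemma, third-person-singular present, subject, complement) — complements
# must stay outside the closed marker vocabulary.
_VERB_BANK = {
    "english": [
        ("rain", "rains", "it", "tomorrow"),
        ("win", "wins", "the team", "on sunday"),
        ("crash", "crashes", "the market", "within two years"),
        ("arrive", "arrives", "the train", "in one week"),
        ("snow", "snows", "it", "in six months"),
        ("retire", "retires", "she", "in ten years"),
        ("move", "moves", "he", "next year"),
        ("grow", "grows", "the city", "over time"),
    ],
    "dutch": [
        ("regenen", "regent", "het", "morgen"),
        ("winnen", "wint", "het team", "zondag"),
        ("komen", "komt", "de trein", "over een week"),
        ("sneeuwen", "sneeuwt", "het", "over zes maanden"),
        ("verhuizen", "verhuist", "hij", "volgend jaar"),
        ("groeien", "groeit", "de stad", "na verloop van tijd"),
        ("spelen", "speelt", "zij", "vanavond"),
        ("stijgen", "stijgt", "de prijs", "over twee jaar"),
    ],
}

# Modal adverbs used for injection; all are in the shipped lexicons.
_INJECT_MODALS = {"english": ["possibly", "probably", "maybe", "definitely"],
                  "dutch": ["misschien", "waarschijnlijk", "mogelijk", "zeker"]}

_FUTURE_AUX = {"english": "will", "dutch": "zal"}


def default_items(language: str, n_items: int) -> list[ElicitationItem]:
    """A bank of elicitation items cycling the verb bank over the design factors."""
    bank = _VERB_BANK[language]
    items = []
    for i in range(n_items):
        lemma, pres, subj, compl = bank[i % len(bank)]
        items.append(ElicitationItem(
            item_id=f"{language[:2]}{i:02d}",
            language=language,
            context_text=f"context {i}: something happens {compl}.",
            target_template=f"{subj} {{{lemma.upper()}}} {compl}",
            target_verb_lemma=lemma,
            present_forms=frozenset({lemma, pres} if language == "english" else {pres}),
            distance_category=DISTANCE_CATEGORIES[i % len(DISTANCE_CATEGORIES)],
            modality_condition=MODALITY_CONDITIONS[i % len(MODALITY_CONDITIONS)],
            ftr_mode=FTR_MODES[i % len(FTR_MODES)],
        ))
    return items


def gen_elicitation(participant_id: str, language: str, fut_proportion: float,
                    items: Sequence[ElicitationItem], lexicon: Lexicon,
                    modal_injection_rate: float, rng: np.random.Generator,
                    ) -> tuple[list[ElicitationResponse], dict[tuple[str, str], FTRScore]]:
    """Template-realized responses plus their ground-truth labels.

    Per item: future-marked template with probability ``fut_proportion``,
    otherwise a present-tense template; independently, a modal adverb is
    spliced in with probability ``modal_injection_rate`` (which makes the
    ground truth 0/0 by modal dominance).
    """
    if lexicon.language != language:
        raise ValueError("lexicon language does not match participant language")
    aux = _FUTURE_AUX[language]
    responses, labels = [], {}
    bank = {entry[0]: entry for entry in _VERB_BANK[language]}
    for item in items:
        if item.target_verb_lemma not in bank:
            raise ValueError(f"no template for verb {item.target_verb_lemma!r}")
        lemma, pres, subj, compl = bank[item.target_verb_lemma]
        use_future = rng.random() < fut_proportion
        inject = rng.random() < modal_injection_rate
        modal = rng.choice(_INJECT_MODALS[language]) if inject else None
        if language == "english":
            if use_future:
                words = [subj, aux, lemma, compl]
                if modal:
                    words.insert(2, modal)
            else:
                words = [subj, pres, compl]
                if modal:
                    words.insert(1, modal)
        else:
            # Dutch V2 order: "het zal morgen regenen" / "het regent morgen"
            if use_future:
                words = [subj, aux, compl, lemma]
                if modal:
                    words.insert(2, modal)
            else:
                words = [subj, pres, compl]
                if modal:
                    words.insert(2, modal)
        text = " ".join(words).capitalize() + "."
        responses.append(ElicitationResponse(participant_id, item.item_id, text))
        if modal:
            labels[(participant_id, item.item_id)] = FTRScore(0, 0)
        elif use_future:
            labels[(participant_id, item.item_id)] = FTRScore(1, 0)
        else:
            labels[(participant_id, item.item_id)] = FTRScore(0, 1)
    return responses, labels


def cohort_elicitation(cohort: pd.DataFrame, items_by_language: dict[str, list[ElicitationItem]],
                       lexicons: dict[str, Lexicon], modal_injection_rate: float,
                       seed: int) -> tuple[list[ElicitationResponse], dict]:
    """Elicitation responses + ground truth for a whole cohort."""
    rng = np.random.default_rng(seed)
    responses: list[ElicitationResponse] = []
    labels: dict[tuple[str, str], FTRScore] = {}
    for row in cohort.itertuples():
        r, l = gen_elicitation(row.participant_id, row.language, row.fut_proportion,
                               items_by_language[row.language], lexicons[row.language],
                               modal_injection_rate, rng)
        responses.extend(r)
        labels.update(l)
    return responses, labels


def with_seed(params: GeneratorParams, seed: int) -> GeneratorParams:
    return replace(params, seed=seed)
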