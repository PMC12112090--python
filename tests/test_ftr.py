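"""Closed-vocabulary future/present coding of elicited sentences."""

import pytest
from hypothesis import given, settings, strategies as st

from ftrdisc.ftr import (
    ElicitationItem, ElicitationResponse, FTRScore, Lexicon, classify_response,
    contains_marker, load_lexicon_text, normalize, score_participants,
    validate_against_labels,
)


def test_normalize_examples(english_lexicon):
    assert normalize("It'll rain tomorrow.", english_lexicon.contraction_map) == \
        ["it", "will", "rain", "tomorrow"]
    assert normalize("Morgen regent het.") == ["morgen", "regent", "het"]
    # parenthetical certainty echoes are stripped before scoring
    assert normalize("It rains (I'm very sure)") == ["it", "rains"]
    assert normalize("He won't win (sadly (really))",
                     english_lexicon.contraction_map) == ["he", "will", "not", "win"]
    assert normalize("Gonna rain", english_lexicon.contraction_map) == ["going", "to", "rain"]


def test_contains_marker():
    assert contains_marker(["it", "is", "going", "to", "rain"], [("going", "to")])
    assert not contains_marker(["the", "bears", "win"], [("will",)])
    assert contains_marker(["het", "zal", "regenen"], [("zal",)])
    # multiword markers must be contiguous
    assert not contains_marker(["going", "there", "to", "win"], [("going", "to")])


@pytest.mark.parametrize("text, future, present", [
    ("It will rain tomorrow", 1, 0),
    ("It will possibly rain tomorrow", 0, 0),   # modal dominance
    ("It rains tomorrow", 0, 1),
    ("It is going to rain tomorrow", 1, 0),
    ("It'll rain tomorrow", 1, 0),
    ("It won't rain tomorrow", 1, 0),           # negated prediction is still future
    ("It might rain tomorrow", 0, 0),
    ("Rain is definitely coming", 0, 0),        # high-certainty modal also dominates
    ("The weather stays dry", 0, 0),            # neither class
])
def test_classify_english(text, future, present, rain_item, english_lexicon):
    score = classify_response(ElicitationResponse("p", "e01", text), rain_item,
                              english_lexicon)
    assert (score.future, score.present) == (future, present)


@pytest.mark.parametrize("text, future, present", [
    ("Morgen regent het", 0, 1),
    ("Het zal morgen regenen", 1, 0),
    ("Het gaat morgen regenen", 1, 0),
    ("Het zal misschien morgen regenen", 0, 0),
    ("Morgen regent het zeker", 0, 0),
])
def test_classify_dutch(text, future, present, regen_item, dutch_lexicon):
    score = classify_response(ElicitationResponse("p", "d01", text), regen_item,
                              dutch_lexicon)
    assert (score.future, score.present) == (future, present)


def test_classify_rejects_language_mismatch(rain_item, dutch_lexicon):
    with pytest.raises(ValueError, match="language"):
        classify_response(ElicitationResponse("p", "e01", "It will rain"),
                          rain_item, dutch_lexicon)


def test_mutual_exclusivity_is_enforced():
    with pytest.raises(ValueError):
        FTRScore(1, 1)


@given(st.sampled_from([
    "It will rain tomorrow", "It rains tomorrow", "It is going to rain tomorrow",
]), st.sampled_from(["possibly", "might", "definitely", "maybe"]),
    st.integers(0, 4))
@settings(derandomize=True)
def test_modal_injection_suppresses_both_classes(text, modal, pos):
    from ftrdisc.ftr import load_lexicon
    lexicon = load_lexicon("english")
    item = _items(1)[0]
    words = text.split()
    words.insert(min(pos, len(words)), modal)
    score = classify_response(ElicitationResponse("p", "i0", " ".join(words)),
                              item, lexicon)
    assert (score.future, score.present) == (0, 0)


def _items(n, language="english", **kw):
    return [ElicitationItem(
        item_id=f"i{j}", language=language, context_text="c",
        target_template="it {RAIN} tomorrow", target_verb_lemma="rain",
        present_forms=frozenset({"rain", "rains"}), **kw) for j in range(n)]


def test_score_participants_proportions(english_lexicon):
    items = _items(10)
    texts = (["It will rain tomorrow"] * 6 + ["It rains tomorrow"] * 2
             + ["It might rain tomorrow"] * 2)
    responses = [ElicitationResponse("p1", f"i{j}", t) for j, t in enumerate(texts)]
    out = score_participants(responses, items, english_lexicon)
    assert len(out) == 1
    assert out[0].fut_proportion == pytest.approx(0.6)
    assert out[0].pres_proportion == pytest.approx(0.2)
    assert out[0].n_scored == 10
    assert out[0].fut_proportion + out[0].pres_proportion <= 1


def test_score_participants_order_insensitive(english_lexicon):
    items = _items(6)
    texts = ["It will rain tomorrow"] * 3 + ["It rains tomorrow"] * 3
    responses = [ElicitationResponse("p1", f"i{j}", t) for j, t in enumerate(texts)]
    fwd = score_participants(responses, items, english_lexicon)
    rev = score_participants(list(reversed(responses)), items, english_lexicon)
    assert fwd == rev


def test_excluded_items_do_not_count(english_lexicon):
    items = _items(2) + [ElicitationItem(
        item_id="ex", language="english", context_text="c",
        target_template="t", target_verb_lemma="rain",
        present_forms=frozenset({"rains"}), excluded=True)]
    responses = [
        ElicitationResponse("p1", "i0", "It will rain tomorrow"),
        ElicitationResponse("p1", "ex", "It will rain tomorrow"),
        ElicitationResponse("p2", "ex", "It will rain tomorrow"),
    ]
    out = score_participants(responses, items, english_lexicon)
    # p2 answered only excluded items: missing, not zero
    assert [s.participant_id for s in out] == ["p1"]
    assert out[0].n_scored == 1
    assert out[0].fut_proportion == 1.0


def test_score_participants_rejects_duplicates(english_lexicon):
    items = _items(1)
    responses = [ElicitationResponse("p1", "i0", "x y"),
                 ElicitationResponse("p1", "i0", "x z")]
    with pytest.raises(ValueError, match="duplicate"):
        score_participants(responses, items, english_lexicon)


def test_validate_against_labels():
    keys = [("p", f"i{j}") for j in range(100)]
    gold = {k: FTRScore(1, 0) for k in keys}
    assert validate_against_labels(gold, gold)["future"]["accuracy"] == 1.0
    all_zero = {k: FTRScore(0, 0) for k in keys}
    m = validate_against_labels(all_zero, gold)
    assert m["future"]["recall"] == 0.0
    # 96 of 100 agree -> accuracy 0.96
    mixed = {k: (FTRScore(1, 0) if j < 96 else FTRScore(0, 0))
             for j, k in enumerate(keys)}
    assert validate_against_labels(mixed, gold)["future"]["accuracy"] == pytest.approx(0.96)
    with pytest.raises(ValueError, match="aligned"):
        validate_against_labels({("p", "i0"): FTRScore(0, 0)}, gold)


def test_lexicon_parsing_and_disjointness():
    lex = load_lexicon_text("english", "[future]\nwill\ngoing to\n[modal]\nmay\n")
    assert ("going", "to") in lex.future_markers
    with pytest.raises(ValueError, match="both"):
        load_lexicon_text("english", "[future]\nwill\n[modal]\nwill\n")
    with pytest.raises(ValueError, match="section"):
        load_lexicon_text("english", "will\n")


def test_adverbial_toggle():
    text = "[future]\nwill\n[modal]\nmay\n[adverbial]\ntomorrow\n"
    off = load_lexicon_text("english", text)
    item = _items(1)[0]
    resp = ElicitationResponse("p", "i0", "it gets cold tomorrow")
    assert classify_response(resp, item, off).future == 0
    on = Lexicon(language=off.language, future_markers=off.future_markers,
                 modal_markers=off.modal_markers, contraction_map=off.contraction_map,
                 adverbial_markers=off.adverbial_markers, adverbials_count_as_future=True)
    assert classify_response(resp, item, on).future == 1
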