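import pytest

from ftrdisc import discounting, ftr


@pytest.fixture(scope="session")
def battery1():
    return discounting.study1_battery()


@pytest.fixture(scope="session")
def battery2():
    return discounting.study2_battery()


@pytest.fixture(scope="session")
def english_lexicon():
    return ftr.load_lexicon("english")


@pytest.fixture(scope="session")
def dutch_lexicon():
    return ftr.load_lexicon("dutch")


@pytest.fixture
def rain_item():
    return ftr.ElicitationItem(
        item_id="e01", language="english", context_text="weather tomorrow",
        target_template="it {RAIN} tomorrow", target_verb_lemma="rain",
        present_forms=frozenset({"rain", "rains"}),
        distance_category="tomorrow", modality_condition="neutral",
        ftr_mode="prediction",
    )


@pytest.fixture
def regen_item():
    return ftr.ElicitationItem(
        item_id="d01", language="dutch", context_text="het weer morgen",
        target_template="morgen {REGENEN} het", target_verb_lemma="regenen",
        present_forms=frozenset({"regent"}),
        distance_category="tomorrow", modality_condition="neutral",
        ftr_mode="prediction",
    )


def noise_free_choices(k, battery, pid="p"):
    """Choice vector a perfectly hyperbolic agent with rate k would produce."""
    return [discounting.ChoiceObservation(pid, it.item_id, discounting.predict_choice(it, k))
            for it in battery]
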