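"""Code the simulated elicitation text and fit discount rates, then report
descriptive marginals and per-language correlations.

Reads the bundles written by 02_simulate_cohorts.py, runs the deterministic
classifier against the ground-truth labels (expected: perfect agreement,
since the generator writes within-vocabulary templates), refits each
participant's k from their choices, and reports how well the single-k
hyperbolic rule predicts the noisy choices.

Writes results/{study}_participants.csv, _descriptives.csv, _correlations.csv.
"""

from pathlib import Path

import pandas as pd

from ftrdisc import discounting, ftr, pipeline

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results"


def main():
    for study in ("study1", "study2"):
        src = SYN / study
        battery = discounting.read_battery(src / "battery.csv")
        choices = discounting.read_choice_observations(src / "choices.csv")
        items_df = pd.read_csv(src / "items.csv")
        responses_df = pd.read_csv(src / "responses.csv")
        truth = pd.read_csv(src / "participants_truth.csv")
        labels_df = pd.read_csv(src / "labels_truth.csv")

        scores = []
        predicted = {}
        for language in ("english", "dutch"):
            lexicon = ftr.load_lexicon(language)
            lang_items = [ftr.ElicitationItem(
                item_id=r.item_id, language=r.language, context_text=r.context_text,
                target_template=r.target_template, target_verb_lemma=r.target_verb_lemma,
                present_forms=frozenset(str(r.present_forms).split("|")),
                distance_category=r.distance_category,
                modality_condition=r.modality_condition,
                ftr_mode=r.ftr_mode, excluded=bool(r.excluded),
            ) for r in items_df.itertuples() if r.language == language]
            ids = {it.item_id for it in lang_items}
            lang_responses = [ftr.ElicitationResponse(str(r.participant_id), r.item_id, r.text)
                              for r in responses_df.itertuples() if r.item_id in ids]
            item_by_id = {it.item_id: it for it in lang_items}
            for resp in lang_responses:
                predicted[(resp.participant_id, resp.item_id)] = \
                    ftr.classify_response(resp, item_by_id[resp.item_id], lexicon)
            scores.extend(ftr.score_participants(lang_responses, lang_items, lexicon))

        gold = {(str(r.participant_id), r.item_id): ftr.FTRScore(r.future, r.present)
                for r in labels_df.itertuples()}
        metrics = ftr.validate_against_labels(predicted, gold)
        print(f"{study}: classifier vs ground truth — "
              f"future acc {metrics['future']['accuracy']:.3f}, "
              f"present acc {metrics['present']['accuracy']:.3f}")

        fits, overall = discounting.cohort_fit(choices, battery)
        print(f"{study}: single-k hyperbolic rule predicts "
              f"{100 * overall:.2f}% of simulated choices")

        languages = dict(zip(truth.participant_id, truth.language))
        participants = pipeline.build_participant_table(scores, fits, languages)
        participants.to_csv(OUT / f"{study}_participants.csv", index=False)
        desc = pipeline.descriptive_table(participants)
        desc.to_csv(OUT / f"{study}_descriptives.csv", index=False)
        corr = pipeline.pearson_correlations(participants)
        corr.to_csv(OUT / f"{study}_correlations.csv", index=False)
        fut = desc[desc.variable == "fut_proportion"].set_index("language")
        print(f"{study}: mean future-tense proportion — "
              f"English {fut.loc['english', 'mean']:.2f}, "
              f"Dutch {fut.loc['dutch', 'mean']:.2f}")


if __name__ == "__main__":
    main()
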