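"""Simulate both studies' cohorts and write the delimited study bundles.

Each bundle contains exactly the files the real pipeline would consume
(items, responses, battery, choices) plus ground-truth sidecars (latent k,
latent propensity, true labels) that only the tests use.

Writes results/synthetic/study{1,2}/*.csv.
"""

from pathlib import Path

import pandas as pd

from ftrdisc import discounting, pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20250

def main():
    for study in ("study1", "study2"):
        bundle = pipeline.simulate_study({"study": study, "seed": SEED})
        out = OUT / study
        out.mkdir(parents=True, exist_ok=True)
        discounting.battery_to_frame(bundle["battery"]).to_csv(out / "battery.csv", index=False)
        pd.DataFrame([o.__dict__ for o in bundle["choices"]]).to_csv(out / "choices.csv", index=False)
        items = [it for lang in bundle["items"].values() for it in lang]
        pd.DataFrame([{**it.__dict__, "present_forms": "|".join(sorted(it.present_forms))}
                      for it in items]).to_csv(out / "items.csv", index=False)
        pd.DataFrame([r.__dict__ for r in bundle["responses"]]).to_csv(out / "responses.csv", index=False)
        bundle["cohort"].to_csv(out / "participants_truth.csv", index=False)
        pd.DataFrame([{"participant_id": k[0], "item_id": k[1],
                       "future": v.future, "present": v.present}
                      for k, v in bundle["labels"].items()]).to_csv(out / "labels_truth.csv", index=False)
        cohort = bundle["cohort"]
        print(f"{study}: n={len(cohort)} "
              f"({(cohort.language == 'english').sum()} English / "
              f"{(cohort.language == 'dutch').sum()} Dutch), "
              f"{len(bundle['responses'])} elicited responses, "
              f"{len(bundle['choices'])} choices -> {out}")


if __name__ == "__main__":
    main()
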