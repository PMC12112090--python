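"""End-to-end orchestration, descriptive reporting, and file schemas.

The full chain is: classify elicited text → per-participant future/present
proportions → fit discount rates from choices → join the two participant
tables → standardize the mediator → sample the mediation posterior → report
path summaries, the four conditional indirect effects, and Bayesian R².
Everything is a pure function of (inputs, config, seed); result files carry
provenance (seed, config hash, package version) and identical reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import __version__, discounting, ftr, mediation, synth

logger = logging.getLogger(__name__)

DEFAULT_HYPOTHESES = {
    "lambda1": "negative",
    "lambda2": "negative",
    "alpha": "positive",
    "tau_prime": "positive",
    "beta1": "negative",
    "beta2": "negative",
    "indirect": "negative",
}

PATH_NAMES = ("lambda1", "lambda2", "alpha", "tau_prime", "beta1", "beta2")
INDIRECT_COMBOS = (("english", "english"), ("english", "dutch"),
                   ("dutch", "english"), ("dutch", "dutch"))


def descriptive_table(participants: pd.DataFrame,
                      variables=("fut_proportion", "pres_proportion", "log_k"),
                      mad_constant: float = 1.4826) -> pd.DataFrame:
    """Mean/SD/median/MAD/min/max/quartiles per variable × language."""
    rows = []
    for var in variables:
        for language, grp in participants.groupby("language", sort=True):
            x = grp[var].to_numpy(dtype=float)
            if x.size == 0:
                raise ValueError(f"empty cell: {var} × {language}")
            rows.append({
                "variable": var,
                "language": language,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "median": float(np.median(x)),
                "mad": float(scipy.stats.median_abs_deviation(x, scale=1 / mad_constant)),
                "min": x.min(),
                "max": x.max(),
                "q25": float(np.quantile(x, 0.25)),
                "q75": float(np.quantile(x, 0.75)),
            })
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def pearson_correlations(participants: pd.DataFrame,
                         variables=("fut_proportion", "pres_proportion", "log_k"),
                         ) -> pd.DataFrame:
    """Per-language pairwise Pearson correlations with two-sided p-values."""
    rows = []
    for language, grp in participants.groupby("language", sort=True):
        if len(grp) < 3:
            raise ValueError(f"need at least 3 participants per language, "
                             f"{language} has {len(grp)}")
        for i, v1 in enumerate(variables):
            for v2 in variables[i + 1:]:
                x, y = grp[v1].to_numpy(float), grp[v2].to_numpy(float)
                if x.std() == 0 or y.std() == 0:
                    raise ValueError(f"zero variance in {v1 if x.std() == 0 else v2} "
                                     f"({language})")
                r, p = scipy.stats.pearsonr(x, y)
                rows.append({"language": language, "var1": v1, "var2": v2,
                             "r": float(r), "p": float(p), "stars": _stars(p)})
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_participant_table(scores: list[ftr.ParticipantFTR],
                            fits: pd.DataFrame,
                            languages: dict[str, str]) -> pd.DataFrame:
    """Join classifier proportions with discount fits, dropping listwise."""
    ftr_df = pd.DataFrame([s.__dict__ for s in scores])
    if ftr_df["participant_id"].duplicated().any():
        raise ValueError("duplicated participant_id in classifier output")
    if fits["participant_id"].duplicated().any():
        raise ValueError("duplicated participant_id in discount fits")
    joined = ftr_df.merge(fits[["participant_id", "k", "log_k", "match_proportion"]],
                          on="participant_id", how="inner")
    dropped = (set(ftr_df.participant_id) | set(fits.participant_id)) - set(joined.participant_id)
    if dropped:
        logger.info("dropped %d participants missing one task: %s",
                    len(dropped), sorted(dropped)[:10])
    joined["language"] = joined["participant_id"].map(languages)
    if joined["language"].isna().any():
        missing = joined.loc[joined.language.isna(), "participant_id"].tolist()
        raise ValueError(f"no language recorded for participants {missing[:5]}")
    joined["language_indicator"] = (joined["language"] == "english").astype(int)
    return joined


def simulate_study(config: dict) -> dict:
    """Generate one synthetic study bundle from the config's simulation block."""
    study = config.get("study", "study1")
    seed = int(config.get("seed", 0))
    overrides = config.get("generator", {}) or {}
    params = synth.default_params(study, seed=seed, **overrides)
    cohort = synth.gen_cohort(params)
    battery = discounting.get_battery(params.battery)
    ss = np.random.SeedSequence(seed)
    choice_seed, elicit_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    choices = synth.cohort_choices(cohort, battery, params.choice_noise, choice_seed)
    lexicons = {lang: ftr.load_lexicon(lang) for lang in ("english", "dutch")}
    items = {lang: synth.default_items(lang, params.n_elicitation_items)
             for lang in ("english", "dutch")}
    responses, labels = synth.cohort_elicitation(cohort, items, lexicons,
                                                 params.modal_injection_rate, elicit_seed)
    return {"params": params, "cohort": cohort, "battery": battery,
            "choices": choices, "items": items, "responses": responses,
            "labels": labels, "lexicons": lexicons}


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Full chain: simulate/load → classify → fit k → join → mediate → report."""
    seed = int(config.get("seed", 0))
    n_draws = int(config.get("n_draws", 4000))
    hypotheses = {**DEFAULT_HYPOTHESES, **(config.get("hypotheses") or {})}

    if config.get("simulate", True):
        bundle = simulate_study(config)
        battery, choices = bundle["battery"], bundle["choices"]
        items = [it for lang_items in bundle["items"].values() for it in lang_items]
        responses, lexicons = bundle["responses"], bundle["lexicons"]
        languages = dict(zip(bundle["cohort"].participant_id, bundle["cohort"].language))
    else:
        inputs = config["inputs"]
        battery = discounting.read_battery(inputs["battery"])
        choices = discounting.read_choice_observations(inputs["choices"])
        items_df = pd.read_csv(inputs["items"])
        items = [ftr.ElicitationItem(
            item_id=str(r.item_id), language=str(r.language),
            context_text=str(r.context_text), target_template=str(r.target_template),
            target_verb_lemma=str(r.target_verb_lemma),
            present_forms=frozenset(str(r.present_forms).split("|")),
            distance_category=str(r.distance_category),
            modality_condition=str(r.modality_condition),
            ftr_mode=str(r.ftr_mode), excluded=bool(r.excluded),
        ) for r in items_df.itertuples()]
        resp_df = pd.read_csv(inputs["responses"])
        responses = [ftr.ElicitationResponse(str(r.participant_id), str(r.item_id),
                                             str(r.text)) for r in resp_df.itertuples()]
        lexicons = {lang: ftr.load_lexicon(lang) for lang in ("english", "dutch")}
        part_df = pd.read_csv(inputs["participants"])
        languages = dict(zip(part_df.participant_id.astype(str), part_df.language))

    # classify per language (items carry their language)
    scores: list[ftr.ParticipantFTR] = []
    item_by_id = {it.item_id: it for it in items}
    by_lang: dict[str, list[ftr.ElicitationResponse]] = {}
    for resp in responses:
        by_lang.setdefault(item_by_id[resp.item_id].language, []).append(resp)
    for lang, lang_responses in sorted(by_lang.items()):
        lang_items = [it for it in items if it.language == lang]
        scores.extend(ftr.score_participants(lang_responses, lang_items, lexicons[lang]))

    fits, overall_match = discounting.cohort_fit(choices, battery)
    participants = build_participant_table(scores, fits, languages)
    if participants.empty:
        raise ValueError("no participants with both tasks; nothing to analyse")

    descriptives = descriptive_table(participants)
    correlations = pearson_correlations(participants)

    rows = participants[["participant_id", "language_indicator", "log_k"]].copy()
    rows["fut_z"] = mediation.zscale(participants["fut_proportion"])
    draws = mediation.fit_mediation(rows, n_draws=n_draws, seed=seed)

    path_summaries = {
        name: mediation.summarize(draws.path(name), hypotheses[name])
        for name in PATH_NAMES
    }
    indirect = {
        f"alpha_{a}.beta_{b}": mediation.summarize(
            mediation.conditional_indirect(draws, a, b), hypotheses["indirect"])
        for a, b in INDIRECT_COMBOS
    }
    coef_means = {name: float(draws.path(name).mean()) for name in PATH_NAMES}
    point = {f"alpha_{a}.beta_{b}": mediation.point_indirect(coef_means, a, b)
             for a, b in INDIRECT_COMBOS}

    cm = np.column_stack([draws.lambda1, draws.alpha])
    _, r2_m = mediation.bayes_r2(cm, draws.sigma1, mediation.mediator_design(rows))
    cy = np.column_stack([draws.lambda2, draws.tau_prime, draws.beta1, draws.beta2])
    _, r2_y = mediation.bayes_r2(cy, draws.sigma2, mediation.outcome_design(rows))

    results = {
        "provenance": {"seed": seed, "config_hash": _config_hash(config),
                       "package_version": __version__},
        "n_participants": int(len(participants)),
        "overall_choice_match": float(overall_match),
        "paths": {k: _summary_dict(v) for k, v in path_summaries.items()},
        "conditional_indirect": {k: _summary_dict(v) for k, v in indirect.items()},
        "point_indirect": point,
        "bayes_r2": {"mediator": r2_m, "outcome": r2_y},
    }
    if out_dir is not None:
        _write_outputs(Path(out_dir), participants, descriptives, correlations, results)
    return {"participants": participants, "descriptives": descriptives,
            "correlations": correlations, "draws": draws, "results": results}


def _summary_dict(s: mediation.MediationSummary) -> dict:
    return {"est": s.est, "ci90": list(s.ci90), "ci95": list(s.ci95),
            "pp": s.pp, "hypothesis_sign": s.hypothesis_sign}


def _write_outputs(out_dir: Path, participants, descriptives, correlations, results):
    out_dir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(out_dir / "participants.csv", index=False)
    descriptives.to_csv(out_dir / "descriptives.csv", index=False)
    correlations.to_csv(out_dir / "correlations.csv", index=False)
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    logger.info("wrote results under %s", out_dir)
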