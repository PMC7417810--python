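"""Synthetic cohort generator.

Samples patients from an eight-profile generating truth (the shipped preset
follows the published prevalences and qualitative profile descriptions),
assigns confounded low/high-intensity episodes — more severe profiles are
more likely to receive high-intensity treatment — and draws end-of-treatment
scores whose change distribution depends on both profile and treatment, so
every downstream analysis stage has realistic structure to detect.

All draws flow from a single root seed, split deterministically per stage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .mixture import IndicatorVector, ProfileModel, default_schema
from .outcomes import EndStatus, EpisodeScores, ScorePair
from .treatment import HI, LI, EpisodeTreatment

__all__ = [
    "GeneratorConfig",
    "PatientRecord",
    "default_preset",
    "load_preset",
    "generate_baseline",
    "assign_treatment",
    "generate_followup",
    "generate_cohort",
]

_STAGE_BASELINE = 0
_STAGE_TREATMENT = 1
_STAGE_FOLLOWUP = 2


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: indicators, episode and episode scores."""

    id: int
    indicators: IndicatorVector
    year: str
    true_profile: int | None = None
    episode: EpisodeTreatment | None = None
    scores: EpisodeScores | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating truth for the synthetic cohort.

    ``model`` holds the mixture parameters (also the allocation truth);
    ``treatment_model`` the per-profile high-intensity probability and the
    per-intensity modality mixes; ``outcome_model`` per-profile,
    per-treatment score-change [mean, sd] pairs, modality adjustments and
    attrition probabilities; ``session_model`` per-intensity Poisson rates.
    """

    model: ProfileModel
    years: dict[str, float]
    treatment_model: dict = field(default_factory=dict)
    outcome_model: dict = field(default_factory=dict)
    session_model: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        yw = sum(self.years.values())
        if abs(yw - 1.0) > 1e-9:
            raise ValueError("year weights must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def load_preset(path_or_stream) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML preset."""
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    schema = default_schema()
    labels = list(raw["labels"])
    cont = schema.continuous_names
    binr = schema.binary_names
    means = np.array([[raw["profiles"][l]["means"][c] for c in cont] for l in labels])
    sds = np.array([[raw["profiles"][l]["sds"][c] for c in cont] for l in labels])
    rates = np.array([[raw["profiles"][l]["rates"][b] for b in binr] for l in labels])
    model = ProfileModel(
        weights=np.array(raw["weights"], float),
        cont_means=means,
        cont_sds=sds,
        bin_rates=rates,
        schema=schema,
        labels=tuple(labels),
    )
    treatment_model = {
        "hi_prob": [raw["profiles"][l]["hi_prob"] for l in labels],
        "li_modalities": dict(raw["li_modalities"]),
        "hi_modalities": dict(raw["hi_modalities"]),
        "step_up_prob": float(raw["step_up_prob"]),
        "second_modality_prob": float(raw["second_modality_prob"]),
        "even_split_prob": float(raw["even_split_prob"]),
    }
    outcome_model = {
        "change": {l: raw["profiles"][l]["change"] for l in labels},
        "modality_change": {l: raw["profiles"][l]["modality_change"] for l in labels},
        "attrition": [raw["profiles"][l]["attrition"] for l in labels],
    }
    session_model = {k: float(v) for k, v in raw["sessions"].items()}
    return GeneratorConfig(
        model=model,
        years={str(k): float(v) for k, v in raw["years"].items()},
        treatment_model=treatment_model,
        outcome_model=outcome_model,
        session_model=session_model,
        missing_rate=float(raw["missing_rate"]),
    )


def default_preset() -> GeneratorConfig:
    """The shipped eight-profile preset."""
    ref = importlib.resources.files("profilemix.data") / "default_preset.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return load_preset(fh)


def generate_baseline(config: GeneratorConfig, n: int, seed: int) -> list[PatientRecord]:
    """Draw ``n`` patients: profile, indicators (rounded + clipped), year.

    Baseline PHQ-9/GAD-7 scores are recorded from the drawn indicator values
    before the missingness injector runs, so every record carries a usable
    baseline score pair.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _rng(seed, _STAGE_BASELINE)
    model = config.model
    schema = model.schema
    C = model.n_profiles
    profiles = rng.choice(C, size=n, p=model.weights)
    bounds = schema.range_array()
    raw = model.cont_means[profiles] + model.cont_sds[profiles] * rng.standard_normal(
        (n, len(schema.continuous_idx))
    )
    cont = np.clip(np.rint(raw), bounds[:, 0], bounds[:, 1])
    binv = (
        rng.random((n, len(schema.binary_idx))) < model.bin_rates[profiles]
    ).astype(float)
    values = np.concatenate([cont, binv], axis=1)

    miss = np.zeros_like(values, bool)
    if config.missing_rate > 0:
        miss = rng.random(values.shape) < config.missing_rate

    year_labels = list(config.years)
    year_idx = rng.choice(len(year_labels), size=n, p=list(config.years.values()))

    ci = {name: k for k, name in enumerate(schema.continuous_names)}
    records = []
    for i in range(n):
        vals = values[i].copy()
        vals[miss[i]] = np.nan
        indicators = IndicatorVector(
            values=tuple(vals.tolist()),
            observed=tuple((~miss[i]).tolist()),
        )
        baseline = ScorePair(
            phq=int(values[i][ci["phq"]]), gad=int(values[i][ci["gad"]])
        )
        records.append(
            PatientRecord(
                id=i,
                indicators=indicators,
                year=year_labels[year_idx[i]],
                true_profile=int(profiles[i]),
                scores=EpisodeScores(baseline=baseline, final=None, n_sessions=0),
            )
        )
    return records


def _draw_modalities(
    n_sessions: int, mix: dict[str, float], tm: dict, rng: np.random.Generator
) -> list[str]:
    names = list(mix)
    probs = np.array(list(mix.values()), float)
    probs /= probs.sum()
    main = names[int(rng.choice(len(names), p=probs))]
    u = rng.random()
    if n_sessions >= 2 and u < tm["even_split_prob"] and n_sessions % 2 == 0:
        other = names[int(rng.choice(len(names), p=probs))]
        if other != main:
            half = n_sessions // 2
            return [other] * half + [main] * half  # no strict majority
    elif n_sessions >= 3 and u < tm["even_split_prob"] + tm["second_modality_prob"]:
        other = names[int(rng.choice(len(names), p=probs))]
        k = int(rng.integers(1, (n_sessions - 1) // 2 + 1))  # minority prefix
        return [other] * k + [main] * (n_sessions - k)
    return [main] * n_sessions


def assign_treatment(
    records: Sequence[PatientRecord], config: GeneratorConfig, seed: int
) -> list[PatientRecord]:
    """Attach an episode (session modalities + intensities) to every record."""
    rng = _rng(seed, _STAGE_TREATMENT)
    tm = config.treatment_model
    hi_prob = np.asarray(tm["hi_prob"], float)
    out = []
    for rec in records:
        p_hi = hi_prob[rec.true_profile]
        intensity = HI if rng.random() < p_hi else LI
        lam = config.session_model[intensity]
        n_sessions = 1 + int(rng.poisson(max(lam - 1.0, 0.0)))
        stepped = rng.random() < tm["step_up_prob"] and n_sessions >= 2
        if stepped:
            n_li = max(1, n_sessions // 2)
            mods_li = _draw_modalities(n_li, tm["li_modalities"], tm, rng)
            mods_hi = _draw_modalities(n_sessions - n_li, tm["hi_modalities"], tm, rng)
            episode = EpisodeTreatment(
                session_modalities=tuple(mods_li + mods_hi),
                session_intensities=tuple([LI] * n_li + [HI] * (n_sessions - n_li)),
            )
        else:
            mix = tm["li_modalities"] if intensity == LI else tm["hi_modalities"]
            mods = _draw_modalities(n_sessions, mix, tm, rng)
            episode = EpisodeTreatment(
                session_modalities=tuple(mods),
                session_intensities=tuple([intensity] * n_sessions),
            )
        out.append(replace(rec, episode=episode))
    return out


def generate_followup(
    records: Sequence[PatientRecord], config: GeneratorConfig, seed: int
) -> list[PatientRecord]:
    """Draw end-of-treatment scores and end status for every record.

    The score change is normal with a (profile, intensity) mean plus a
    modality adjustment when the episode has a single-intensity main
    modality; results are rounded and clipped to the instrument ranges.
    """
    from .treatment import classify_intensity, main_modality

    rng = _rng(seed, _STAGE_FOLLOWUP)
    om = config.outcome_model
    labels = config.model.labels
    out = []
    for rec in records:
        lab = labels[rec.true_profile]
        intensity = classify_intensity(rec.episode)
        key = HI if intensity == "mixed" else intensity
        ch = om["change"][lab][key]
        d_phq_mu, d_phq_sd = ch["phq"]
        d_gad_mu, d_gad_sd = ch["gad"]
        if intensity != "mixed":
            mod = main_modality(rec.episode)
            if mod is not None and mod in om["modality_change"][lab]:
                adj = om["modality_change"][lab][mod]
                d_phq_mu += adj["phq"]
                d_gad_mu += adj["gad"]
        base = rec.scores.baseline
        phq_f = int(np.clip(round(base.phq + d_phq_mu + d_phq_sd * rng.standard_normal()), 0, 27))
        gad_f = int(np.clip(round(base.gad + d_gad_mu + d_gad_sd * rng.standard_normal()), 0, 21))
        attr_p = om["attrition"][rec.true_profile]
        if rng.random() < attr_p:
            status = EndStatus.DECLINED if rng.random() < 0.3 else EndStatus.DROPPED_OUT
        else:
            status = EndStatus.COMPLETED
        n_sessions = rec.episode.n_sessions
        final = ScorePair(phq=phq_f, gad=gad_f) if n_sessions >= 2 else None
        scores = EpisodeScores(
            baseline=base,
            final=final,
            n_sessions=n_sessions,
            end_status=status,
        )
        out.append(replace(rec, scores=scores))
    return out


def generate_cohort(
    config: GeneratorConfig, n: int | None = None, seed: int | None = None
) -> list[PatientRecord]:
    """Full generation pipeline: baseline, treatment assignment, follow-up."""
    n = config.n if n is None else n
    seed = config.seed if seed is None else seed
    records = generate_baseline(config, n, seed)
    records = assign_treatment(records, config, seed)
    return generate_followup(records, config, seed)
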