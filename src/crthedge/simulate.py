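"""Seeded generator of labelled MEDLINE-format corpora.

The generator emulates the statistical structure of a hand-searched
gold-standard pool: a large corpus of health-journal articles containing a
small minority of cluster randomized trials (CRTs), whose design is
sometimes flagged explicitly in the title/abstract (CLEAR), sometimes only
via the unit of randomization (UNIT), and sometimes not at all (NONE),
with the CLEAR fraction rising over publication years.  Publication-type
indexing is imperfect: a trial carries the "Randomized Controlled Trial"
tag only with configurable probability.  Non-CRT articles mix
individually randomized trials (which also carry the tag and supply
distractor phrasing such as "patients in the participating hospitals were
randomly assigned"), health-promotion/programme-evaluation articles
(which carry the broad MeSH headings and "intervention" textwords that
cost the broad filters their precision), and unrelated articles.

Text is template-based, not free-form: determinism under a seed and exact
consistency between a citation's text and its identifiability label are
worth more here than linguistic realism.  Every generated CLEAR citation
classifies CLEAR, every UNIT citation UNIT, every NONE citation NONE
under :func:`crthedge.identify.classify_identifiability`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .records import (
    Citation,
    Corpus,
    GoldLabels,
    Identifiability,
    LabelRecord,
    ValidationError,
)

_DEFAULT_YEARS = tuple(range(2000, 2008))
# Per-year CRT volume and CLEAR probability mirroring the gold-standard
# pool's trend table (totals 14,16,9,19,15,20,52,17; CLEAR 4,1,1,10,8,13,30,11).
_DEFAULT_CRT_YEAR_WEIGHTS = (14, 16, 9, 19, 15, 20, 52, 17)
_DEFAULT_CLEAR_PROB = {
    2000: 4 / 14,
    2001: 1 / 16,
    2002: 1 / 9,
    2003: 10 / 19,
    2004: 8 / 15,
    2005: 13 / 20,
    2006: 30 / 52,
    2007: 11 / 17,
}


@dataclass(frozen=True)
class PhraseBank:
    """Template sentences per identifiability class.

    ``{design}`` expands to a design phrase ("cluster randomised" etc.),
    ``{units}``/``{unit}`` to a unit noun, ``{randomized}``/
    ``{randomization}`` to a spelling variant, and the remaining
    placeholders to innocuous fillers.  CLEAR templates must classify
    CLEAR, NONE templates NONE, and distractor templates (used for
    individually randomized trials) must never classify CLEAR.
    """

    clear_title: tuple[str, ...] = (
        "A {design} trial of {topic}",
        "{Design} trial of {topic} in {setting}",
    )
    clear_abstract: tuple[str, ...] = (
        "We conducted a {design} trial of {topic} in {setting}.",
        "In this {design} trial, {topic} was compared with usual care.",
    )
    unit_abstract: tuple[str, ...] = (
        "{Units} were {randomized} to active or control arms.",
        "Patients were {randomized} by {unit}.",
        "{Randomization} by {unit} was used to avoid contamination.",
    )
    none_abstract: tuple[str, ...] = (
        "Participants were randomly assigned to active or usual care.",
        "Allocation was determined centrally before baseline assessment.",
    )
    distractor_abstract: tuple[str, ...] = (
        "Patients in the participating {units} were randomly assigned to {drug} or placebo.",
    )
    irt_abstract: tuple[str, ...] = (
        "Patients were randomly assigned to {drug} or placebo.",
        "Participants were randomly allocated to {drug} or placebo.",
    )
    false_clear: tuple[str, ...] = (
        "Prior cluster randomised trials motivated this work.",
        "Evidence from group randomized studies is summarised.",
    )
    community_intervention: str = "A community intervention model guided delivery."

    intervention_sentences: tuple[str, ...] = (
        "The intervention consisted of educational outreach and reminders.",
        "Interventions included tailored feedback and printed materials.",
    )


DEFAULT_PHRASE_BANK = PhraseBank()

_TOPICS = (
    "smoking cessation",
    "hand hygiene promotion",
    "vaccination uptake",
    "diabetes self management",
    "antibiotic prescribing feedback",
    "depression screening",
    "dietary counselling",
    "fall prevention",
)
_SETTINGS = (
    "primary care",
    "urban districts",
    "rural areas",
    "outpatient services",
    "workplaces",
)
_OUTCOMES = (
    "smoking abstinence",
    "glycaemic control",
    "vaccination coverage",
    "prescribing rates",
    "blood pressure",
)
_UNIT_PLURALS = ("schools", "practices", "hospitals", "villages", "wards", "teams", "churches")
_UNIT_SINGULARS = ("physician", "practice", "hospital", "school", "village")
_DRUGS = ("metformin", "a statin", "inhaled corticosteroids", "an ACE inhibitor")
_CONDITIONS = ("type 2 diabetes", "hypertension", "asthma", "chronic heart failure")
_PROCEDURES = ("hip arthroplasty", "cataract surgery", "coronary angiography")
_JOURNALS = (
    "Journal of Preventive Health",
    "Annals of Trial Methodology",
    "International Journal of Care Research",
    "Archives of Population Studies",
    "Clinical Outcomes Quarterly",
)
_MESH_SUBHEADINGS = ("methods", "organization & administration", "statistics & numerical data", "trends")
_DESIGN_FAMILIES = ("cluster", "community", "group")


@dataclass
class GeneratorConfig:
    """Everything that shapes a synthetic corpus.

    Defaults reproduce the gold-standard pool's structure: 25,707
    articles at CRT prevalence 162/25707; CLEAR probability per year
    following the published trend, the non-CLEAR mass split UNIT:NONE =
    46:38; publication-type tagging sensitivity 0.938 for all trials; and
    a non-CRT mix whose rates are chosen so the publication-type filter
    retrieves ~6% of non-CRTs and the broad term block retrieves ~14%.
    """

    n_articles: int = 25707
    crt_prevalence: float = 162 / 25707
    years: tuple[int, ...] = _DEFAULT_YEARS
    crt_year_weights: tuple[float, ...] = _DEFAULT_CRT_YEAR_WEIGHTS
    noncrt_year_weights: tuple[float, ...] | None = None  # None = uniform
    clear_prob_by_year: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLEAR_PROB)
    )
    unit_share_of_unclear: float = 46 / 84
    pt_tag_sensitivity: float = 0.938
    clear_family_weights: tuple[float, ...] = (59, 16, 9)  # cluster : community : group
    clear_in_title_prob: float = 0.6

    # non-CRT composition: individually randomized trials, health-promotion /
    # programme-evaluation articles, unrelated articles
    noncrt_mix: tuple[float, float, float] = (0.065, 0.15, 0.785)

    crt_intervention_rate: float = 0.858
    crt_mesh_rates: dict[str, float] = field(
        default_factory=lambda: {
            "Cluster Analysis": 0.185,
            "Health Promotion": 0.235,
            "Program Evaluation": 0.222,
            "Health Education": 0.198,
        }
    )
    hp_mesh_rates: dict[str, float] = field(
        default_factory=lambda: {
            "Cluster Analysis": 0.031,
            "Health Promotion": 0.198,
            "Program Evaluation": 0.137,
            "Health Education": 0.103,
        }
    )
    hp_intervention_rate: float = 0.30
    hp_community_intervention_rate: float = 0.02
    irt_intervention_rate: float = 0.25
    irt_distractor_rate: float = 0.30
    unrelated_intervention_rate: float = 0.06
    unrelated_animal_rate: float = 0.10
    noncrt_false_clear_rate: float = 0.002
    mesh_major_topic_rate: float = 0.3
    mesh_subheading_rate: float = 0.4
    oversample_2006: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles <= 0:
            raise ValidationError("n_articles must be positive")
        probs = {
            "crt_prevalence": self.crt_prevalence,
            "unit_share_of_unclear": self.unit_share_of_unclear,
            "pt_tag_sensitivity": self.pt_tag_sensitivity,
            "clear_in_title_prob": self.clear_in_title_prob,
            "crt_intervention_rate": self.crt_intervention_rate,
            "hp_intervention_rate": self.hp_intervention_rate,
            "hp_community_intervention_rate": self.hp_community_intervention_rate,
            "irt_intervention_rate": self.irt_intervention_rate,
            "irt_distractor_rate": self.irt_distractor_rate,
            "unrelated_intervention_rate": self.unrelated_intervention_rate,
            "unrelated_animal_rate": self.unrelated_animal_rate,
            "noncrt_false_clear_rate": self.noncrt_false_clear_rate,
            "mesh_major_topic_rate": self.mesh_major_topic_rate,
            "mesh_subheading_rate": self.mesh_subheading_rate,
            **{f"clear_prob[{y}]": p for y, p in self.clear_prob_by_year.items()},
            **{f"crt_mesh[{k}]": v for k, v in self.crt_mesh_rates.items()},
            **{f"hp_mesh[{k}]": v for k, v in self.hp_mesh_rates.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} = {p} outside [0, 1]")
        if abs(sum(self.noncrt_mix) - 1.0) > 1e-9 or min(self.noncrt_mix) < 0:
            raise ValidationError("noncrt_mix proportions must be >= 0 and sum to 1")
        if len(self.crt_year_weights) != len(self.years):
            raise ValidationError("crt_year_weights must match years")
        if min(self.crt_year_weights) < 0 or sum(self.crt_year_weights) <= 0:
            raise ValidationError("crt_year_weights must be non-negative, not all zero")
        if self.noncrt_year_weights is not None and (
            len(self.noncrt_year_weights) != len(self.years)
            or min(self.noncrt_year_weights) < 0
            or sum(self.noncrt_year_weights) <= 0
        ):
            raise ValidationError("invalid noncrt_year_weights")
        missing = [y for y in self.years if y not in self.clear_prob_by_year]
        if missing:
            raise ValidationError(f"clear_prob_by_year missing years: {missing}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        kwargs = dict(data)
        for key in ("years", "crt_year_weights", "noncrt_mix", "clear_family_weights"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("noncrt_year_weights") is not None:
            kwargs["noncrt_year_weights"] = tuple(kwargs["noncrt_year_weights"])
        if "clear_prob_by_year" in kwargs:
            kwargs["clear_prob_by_year"] = {
                int(k): float(v) for k, v in kwargs["clear_prob_by_year"].items()
            }
        return cls(**kwargs)


def _pick(rng: np.random.Generator, items) -> str:
    return items[int(rng.integers(len(items)))]


def _spelling(rng: np.random.Generator) -> tuple[str, str]:
    if rng.random() < 0.5:
        return "randomised", "Randomisation"
    return "randomized", "Randomization"


def sample_citation_text(
    is_crt: bool,
    identifiability: Identifiability,
    year: int,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
    bank: PhraseBank = DEFAULT_PHRASE_BANK,
    *,
    subclass: str = "",
    with_intervention: bool | None = None,
) -> tuple[str, str]:
    """Draw a (title, abstract) pair consistent with the given label.

    For non-CRTs ``subclass`` selects the article family ("irt", "hp",
    "unrelated", "animal"); identifiability must then be NA.
    """
    config = config or GeneratorConfig()
    topic = _pick(rng, _TOPICS)
    setting = _pick(rng, _SETTINGS)
    outcome = _pick(rng, _OUTCOMES)
    randomized, randomization = _spelling(rng)
    sentences: list[str] = []
    title = ""

    if is_crt:
        background = f"We evaluated whether {topic} improves {outcome} in {setting}."
        sentences.append(background)
        if identifiability is Identifiability.CLEAR:
            family = _DESIGN_FAMILIES[
                int(
                    rng.choice(
                        len(_DESIGN_FAMILIES),
                        p=np.asarray(config.clear_family_weights, float)
                        / sum(config.clear_family_weights),
                    )
                )
            ]
            design = f"{family} {randomized}"
            tmpl = _pick(rng, bank.clear_abstract)
            sentences.append(
                tmpl.format(design=design, topic=topic, setting=setting)
            )
            if rng.random() < config.clear_in_title_prob:
                ttmpl = _pick(rng, bank.clear_title)
                title = ttmpl.format(
                    design=design,
                    Design=design.capitalize(),
                    topic=topic,
                    setting=setting,
                )
        elif identifiability is Identifiability.UNIT:
            tmpl = _pick(rng, bank.unit_abstract)
            units = _pick(rng, _UNIT_PLURALS)
            sentences.append(
                tmpl.format(
                    Units=units.capitalize(),
                    units=units,
                    unit=_pick(rng, _UNIT_SINGULARS),
                    randomized=randomized,
                    Randomization=randomization,
                )
            )
        else:
            sentences.append(_pick(rng, bank.none_abstract))
        if with_intervention:
            sentences.append(_pick(rng, bank.intervention_sentences))
        sentences.append("After 12 months the primary outcome improved in the active arm.")
        if not title:
            title = f"Effect of {topic} on {outcome}: a {randomized} controlled trial"
        return title, " ".join(sentences)

    # non-CRT families
    if subclass == "irt":
        drug = _pick(rng, _DRUGS)
        condition = _pick(rng, _CONDITIONS)
        title = f"{drug.capitalize()} for {condition}: a {randomized} controlled trial"
        if rng.random() < config.irt_distractor_rate:
            tmpl = _pick(rng, bank.distractor_abstract)
            sentences.append(tmpl.format(units=_pick(rng, _UNIT_PLURALS), drug=drug))
        else:
            sentences.append(_pick(rng, bank.irt_abstract).format(drug=drug))
        if with_intervention:
            sentences.append(_pick(rng, bank.intervention_sentences))
        sentences.append(f"The primary endpoint was {outcome} at one year.")
    elif subclass == "hp":
        title = f"Evaluation of a {topic} programme in {setting}"
        sentences.append(
            f"We describe the implementation and reach of a {topic} programme."
        )
        if rng.random() < config.hp_community_intervention_rate:
            sentences.append(bank.community_intervention)
        if with_intervention:
            sentences.append(_pick(rng, bank.intervention_sentences))
        sentences.append("Uptake was assessed through routine records.")
    elif subclass == "animal":
        drug = _pick(rng, _DRUGS)
        condition = _pick(rng, _CONDITIONS)
        title = f"{drug.capitalize()} in a murine model of {condition}"
        sentences.append(f"We examined the effects of {drug} in a murine model.")
    else:  # unrelated human article
        condition = _pick(rng, _CONDITIONS)
        title = f"Outcomes of {_pick(rng, _PROCEDURES)} in patients with {condition}"
        sentences.append("We retrospectively reviewed consecutive cases from one centre.")
        if with_intervention:
            sentences.append("No structured intervention was offered during follow up.")
        sentences.append(f"Complication rates were compared by {outcome}.")
    return title, " ".join(sentences)


def _decorate_mesh(heading: str, rng: np.random.Generator, config: GeneratorConfig) -> str:
    out = heading
    if rng.random() < config.mesh_subheading_rate:
        out = f"{out}/{_pick(rng, _MESH_SUBHEADINGS)}"
    if rng.random() < config.mesh_major_topic_rate:
        out = f"*{out}"
    return out


def generate_corpus(config: GeneratorConfig | None = None) -> tuple[Corpus, GoldLabels]:
    """Generate a labelled corpus; deterministic for a given config + seed."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    years = list(config.years)
    crt_w = np.asarray(config.crt_year_weights, float)
    crt_w = crt_w / crt_w.sum()
    if config.noncrt_year_weights is not None:
        non_w = np.asarray(config.noncrt_year_weights, float)
    elif config.oversample_2006 and 2006 in years:
        non_w = np.ones(len(years))
        non_w[years.index(2006)] = len(years) - 1  # roughly triple weight on 2006
    else:
        non_w = np.ones(len(years))
    non_w = non_w / non_w.sum()
    mix = np.asarray(config.noncrt_mix, float)

    corpus = Corpus(provenance=f"synthetic corpus (seed={config.seed})")
    labels = GoldLabels()

    for i in range(config.n_articles):
        uid = f"{10000001 + i:08d}"
        journal = _pick(rng, _JOURNALS)
        is_crt = rng.random() < config.crt_prevalence
        mesh: list[str] = []
        pts: list[str] = ["Journal Article"]

        if is_crt:
            year = years[int(rng.choice(len(years), p=crt_w))]
            if rng.random() < config.clear_prob_by_year[year]:
                ident = Identifiability.CLEAR
            elif rng.random() < config.unit_share_of_unclear:
                ident = Identifiability.UNIT
            else:
                ident = Identifiability.NONE
            with_int = rng.random() < config.crt_intervention_rate
            title, abstract = sample_citation_text(
                True, ident, year, rng, config, with_intervention=with_int
            )
            mesh.append("Humans")
            for heading, rate in config.crt_mesh_rates.items():
                if rng.random() < rate:
                    mesh.append(_decorate_mesh(heading, rng, config))
            if rng.random() < config.pt_tag_sensitivity:
                pts.append("Randomized Controlled Trial")
            labels.add(uid, LabelRecord(True, ident, year))
        else:
            year = years[int(rng.choice(len(years), p=non_w))]
            sub_idx = int(rng.choice(3, p=mix))
            subclass = ("irt", "hp", "unrelated")[sub_idx]
            if subclass == "irt":
                with_int = rng.random() < config.irt_intervention_rate
                title, abstract = sample_citation_text(
                    False, Identifiability.NA, year, rng, config,
                    subclass="irt", with_intervention=with_int,
                )
                mesh.append("Humans")
                if rng.random() < config.pt_tag_sensitivity:
                    pts.append("Randomized Controlled Trial")
            elif subclass == "hp":
                with_int = rng.random() < config.hp_intervention_rate
                title, abstract = sample_citation_text(
                    False, Identifiability.NA, year, rng, config,
                    subclass="hp", with_intervention=with_int,
                )
                mesh.append("Humans")
                for heading, rate in config.hp_mesh_rates.items():
                    if rng.random() < rate:
                        mesh.append(_decorate_mesh(heading, rng, config))
                if rng.random() < 0.3:
                    pts.append("Evaluation Study")
            else:
                animal = rng.random() < config.unrelated_animal_rate
                with_int = rng.random() < config.unrelated_intervention_rate
                title, abstract = sample_citation_text(
                    False, Identifiability.NA, year, rng, config,
                    subclass="animal" if animal else "unrelated",
                    with_intervention=with_int,
                )
                mesh.append("Animals" if animal else "Humans")
            if subclass in ("hp", "unrelated") and rng.random() < config.noncrt_false_clear_rate:
                abstract = abstract + " " + _pick(rng, DEFAULT_PHRASE_BANK.false_clear)
            labels.add(uid, LabelRecord(False, Identifiability.NA, year))

        corpus.add(
            Citation(
                uid=uid,
                title=title,
                abstract=abstract,
                mesh_terms=mesh,
                pub_types=pts,
                journal=journal,
                year=year,
            )
        )
    return corpus, labels
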