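"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators stand in for the unavailable study corpus:

* :func:`sample_vmf_mixture` — unit-norm embedding vectors with planted
  cluster structure, drawn from a mixture of von Mises–Fisher components on
  the sphere. Concentration κ controls how tight each planted cluster is
  (κ = 0 is uniform on the sphere, the structureless null); component means
  are kept apart by a minimum pairwise angle so recovery targets are well
  posed. The default stress scale mirrors the study: n = 3,582 items split
  1,937 train / 1,645 test.
* :func:`generate_question_corpus` — question records built from paraphrase
  templates keyed to the top-level SDOH categories of the bundled taxonomy,
  with randomized section paths and injected exact duplicates under
  different paths, so deduplication and end-to-end clustering are
  exercisable with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import vonmises_fisher

from .corpus_io import QuestionRecord
from ._utils import l2_normalize_rows

#: Study-scale defaults for stress tests.
STUDY_N = 3582
STUDY_TRAIN_SIZE = 1937
STUDY_TEST_SIZE = 1645


@dataclass
class PlantedDataset:
    X: np.ndarray  # n×d unit rows
    labels: np.ndarray  # length-n ints in [0, k)
    means: np.ndarray  # k×d unit rows
    kappa: float
    weights: np.ndarray
    seed: int

    @property
    def min_mean_separation(self) -> float:
        """Smallest pairwise angle (radians) between component means."""
        sims = self.means @ self.means.T
        np.fill_diagonal(sims, -1.0)
        return float(np.arccos(np.clip(sims.max(), -1.0, 1.0)))


@dataclass
class SyntheticCorpus:
    records: list[QuestionRecord]
    true_category: dict[str, str]
    templates_used: dict[str, list[str]]


def _uniform_sphere(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    return l2_normalize_rows(rng.standard_normal((n, d)))


def sample_vmf_mixture(
    n: int,
    d: int,
    k: int,
    kappa: float,
    weights: list[float] | None = None,
    seed: int = 0,
    min_separation_deg: float = 75.0,
    max_retries: int = 200,
) -> PlantedDataset:
    """Draw a planted von Mises–Fisher mixture on the unit sphere.

    Component means are sampled uniformly on the sphere subject to a minimum
    pairwise angle; points come from the vMF distribution around each mean
    (uniform when κ = 0). Deterministic for a fixed seed.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if weights is None:
        weights = [1.0 / k] * k
    weights = np.asarray(weights, dtype=float)
    if weights.size != k or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be a length-k probability vector")
    rng = np.random.default_rng(seed)

    min_cos = np.cos(np.deg2rad(min_separation_deg))
    means = None
    for _ in range(max_retries):
        cand = _uniform_sphere(rng, k, d)
        sims = cand @ cand.T
        np.fill_diagonal(sims, -1.0)
        if k == 1 or sims.max() < min_cos:
            means = cand
            break
    if means is None:
        raise ValueError(
            f"could not place {k} means at >= {min_separation_deg} deg separation "
            f"in {d} dimensions after {max_retries} tries"
        )

    labels = rng.choice(k, size=n, p=weights)
    X = np.empty((n, d))
    for j in range(k):
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            continue
        if kappa == 0:
            X[idx] = _uniform_sphere(rng, idx.size, d)
        else:
            X[idx] = vonmises_fisher(mu=means[j], kappa=kappa).rvs(idx.size, random_state=rng)
    return PlantedDataset(
        X=l2_normalize_rows(X),
        labels=labels,
        means=means,
        kappa=float(kappa),
        weights=weights,
        seed=seed,
    )


# Paraphrase templates per top-level SDOH category: >= 2 wordings each, with
# section-path variants so the same question recurs under different titles.
TEMPLATE_BANK: dict[str, dict[str, list[str]]] = {
    "Health": {
        "questions": [
            "Have you been tested for HIV in the past year",
            "How many hours of sleep do you usually get",
            "Do you currently take any prescribed medication",
            "Have you ever received treatment for substance use",
        ],
        "paraphrases": [
            "HIV test within the last 12 months",
            "Usual nightly hours of sleep",
            "Current prescription medications",
            "Prior substance use treatment episodes",
        ],
        "paths": ["medical/General Health/", "Health Assessment/", "medical/History/"],
    },
    "Family": {
        "questions": [
            "Do you live with your children",
            "Is there a family history of mental illness",
            "Who do you consider your main support person",
        ],
        "paraphrases": [
            "Children living in the household",
            "Family history of psychiatric conditions",
            "Primary support system member",
        ],
        "paths": ["social/Family/", "Family Information/", "social/Relationships/"],
    },
    "Education": {
        "questions": [
            "What Is The Highest Grade You Have Completed",
            "Can you read and write in English",
            "Have you completed any vocational training",
        ],
        "paraphrases": [
            "Highest grade attained",
            "English literacy reading and writing",
            "Vocational training completed",
        ],
        "paths": ["economic/Education/", "Educational Data/", "social/Education History/"],
    },
    "Employment": {
        "questions": [
            "Are you currently employed full time or part time",
            "What is your total monthly income",
            "Do you have health insurance coverage",
        ],
        "paraphrases": [
            "Current employment status",
            "Monthly income from all sources",
            "Health insurance or medicaid coverage",
        ],
        "paths": ["economic/Employment/", "Employment Data/", "economic/Finances/"],
    },
    "Housing": {
        "questions": [
            "What is your current living situation",
            "How many people live in your household",
            "Do you have reliable transportation",
        ],
        "paraphrases": [
            "Current housing arrangement",
            "Number of household members",
            "Access to transportation",
        ],
        "paths": ["social/Housing/", "Housing Information/", "social/Community/"],
    },
    "Legal": {
        "questions": [
            "Have you ever been arrested or convicted",
            "Are you currently on parole or probation",
            "Have you ever been incarcerated",
        ],
        "paraphrases": [
            "Prior arrests or convictions",
            "Current parole or probation status",
            "History of jail or prison time",
        ],
        "paths": ["legal/History/", "Legal Data/", "legal/Status/"],
    },
    "Leisure": {
        "questions": [
            "What do you do in your free time",
            "Do you have any hobbies or interests",
        ],
        "paraphrases": [
            "Free time activities",
            "Hobbies and interests",
        ],
        "paths": ["social/Leisure/", "Leisure Activities/"],
    },
    "Demographics": {
        "questions": [
            "What is your date of birth",
            "What is your race or ethnicity",
        ],
        "paraphrases": [
            "Date of birth",
            "Race and ethnicity",
        ],
        "paths": ["Demographics/", "intake/Demographics/"],
    },
    "Military": {
        "questions": [
            "Have you ever served in the armed forces",
            "Are you a veteran",
        ],
        "paraphrases": [
            "Military service history",
            "Veteran status",
        ],
        "paths": ["social/Military/", "Military Service/"],
    },
    "Spirituality": {
        "questions": [
            "Is religion or spirituality important to you",
            "Do you attend religious services",
        ],
        "paraphrases": [
            "Importance of spirituality",
            "Religious service attendance",
        ],
        "paths": ["social/Spirituality/", "Spiritual Life/"],
    },
}


def generate_question_corpus(
    categories: list[str],
    n_per_category: int,
    seed: int = 0,
    duplicate_rate: float = 0.2,
) -> SyntheticCorpus:
    """Template-filled question records with known category labels.

    Each record draws a wording (base question or paraphrase) and a section
    path from its category's bank; with probability ``duplicate_rate`` a
    record reuses a previously emitted wording under a *different* path, so
    text-only deduplication collapses more keys than path+text dedup.
    Deterministic for a fixed seed.
    """
    unknown = [c for c in categories if c not in TEMPLATE_BANK]
    if unknown:
        raise ValueError(f"unknown categories: {unknown}; known: {sorted(TEMPLATE_BANK)}")
    rng = np.random.default_rng(seed)
    records: list[QuestionRecord] = []
    true_category: dict[str, str] = {}
    templates_used: dict[str, list[str]] = {c: [] for c in categories}
    emitted: dict[str, list[tuple[str, str]]] = {c: [] for c in categories}  # (text, path)
    idx = 0
    for cat in categories:
        bank = TEMPLATE_BANK[cat]
        wordings = bank["questions"] + bank["paraphrases"]
        paths = bank["paths"]
        for _ in range(n_per_category):
            prior = emitted[cat]
            if prior and rng.random() < duplicate_rate:
                text, old_path = prior[int(rng.integers(len(prior)))]
                alt = [p for p in paths if p != old_path]
                path = alt[int(rng.integers(len(alt)))] if alt else old_path
            else:
                text = wordings[int(rng.integers(len(wordings)))]
                path = paths[int(rng.integers(len(paths)))]
            rid = f"s{idx:05d}"
            records.append(
                QuestionRecord(
                    record_id=rid,
                    form_id=f"synthetic-form-{int(rng.integers(1, 6))}",
                    field_path=path,
                    field_name=text,
                )
            )
            true_category[rid] = cat
            if text not in templates_used[cat]:
                templates_used[cat].append(text)
            emitted[cat].append((text, path))
            idx += 1
    return SyntheticCorpus(records=records, true_category=true_category, templates_used=templates_used)


def make_reference_taxonomy(corpus: SyntheticCorpus, n_distractors: int = 0) -> list[str]:
    """Reference measure names: one per planted category plus distractors.

    Names echo the category wording (e.g. "Education measures") so an
    encoder that places related strings nearby maps each planted category to
    its own reference; distractor names are deliberately unrelated strings.
    Deterministic given the corpus.
    """
    cats = sorted(set(corpus.true_category.values()))
    names = [f"{c} measures" for c in cats]
    distractors = [
        "Quasar luminosity catalog",
        "Tectonic plate drift survey",
        "Deep sea sonar calibration",
        "Satellite orbital debris index",
        "Volcanic ash dispersion model",
    ]
    if n_distractors > len(distractors):
        raise ValueError(f"at most {len(distractors)} distractors available")
    return names + distractors[:n_distractors]
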