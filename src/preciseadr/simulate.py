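"""Synthetic FAERS-like cohort generation with planted, recoverable signals.

The generator emulates the structure of a spontaneous-reporting cohort:
multi-disease, multi-drug, multi-ADR reports with demographics, skewed
entity popularity, and sparse planted effects. Each ADR s is drawn per
patient i from a logistic model on the log-odds scale,

    logit P(s in adrs_i) = beta0_s + sum_{m in drugs_i} beta_{m,s}
                           + lambda^g_s * 1[female] + lambda^a_{s,group(age)},

optionally ORed with a spurious-mention noise process of rate
``noise_rate``. Patients whose sampled ADR set comes up empty are
discarded and resampled — a safety report, by construction, always
contains at least one event — which preserves the conditional model for
retained reports.

The planted nonzero coefficients are returned as :class:`GroundTruth`
so recovery can be scored: the mining pipeline should flag the ADRs with
nonzero demographic effects, and predictive models should exploit the
drug effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import AdverseEventReport

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "please_like_spec",
           "AGE_GROUPS", "age_group"]

#: age strata used throughout: child < 18, adult 18-64, elderly >= 65
AGE_GROUPS = ("child", "adult", "elderly")
AGE_BINS = (18, 65)

# full-size PLEASE-like cohort dimensions the scaled spec interpolates from
FULL_N_REPORTS = 279_299
FULL_N_ADRS = 889
FULL_N_DISEASES = 1059
FULL_N_DRUGS = 978


def age_group(age: float) -> int:
    """0 = child (<18), 1 = adult (18-64), 2 = elderly (>=65)."""
    return int(np.digitize(age, AGE_BINS))


@dataclass
class CohortSpec:
    """All knobs of the synthetic-report generator.

    Effects are log-odds increments: ``drug_effect[m, s]`` adds to ADR s
    whenever drug m was taken; ``gender_effect[s]`` applies to female
    patients (sex code 2); ``age_effect[s, g]`` applies per age group
    (child/adult/elderly), with the adult column conventionally zero.
    """

    n_patients: int
    n_diseases: int
    n_drugs: int
    n_adrs: int
    base_adr_logit: np.ndarray                  # (n_adrs,)
    drug_effect: np.ndarray                     # (n_drugs, n_adrs)
    gender_effect: np.ndarray                   # (n_adrs,)
    age_effect: np.ndarray                      # (n_adrs, 3)
    p_female: float = 0.6
    # child/adult/elderly Gaussian mixture over ages, truncated to [0, 100]
    age_mixture: tuple = ((0.1, 9.0, 4.0), (0.6, 42.0, 12.0), (0.3, 74.0, 7.0))
    diseases_per_patient_rate: float = 1.0      # extra diseases ~ Poisson
    extra_drug_prob: float = 0.5                # drugs/disease = 1 + Bernoulli
    zipf_exponent: float = 1.2                  # popularity skew
    candidates_per_disease: int = 4             # disease -> drug menu size
    weight_mean: float = 72.0
    weight_sd: float = 16.0
    p_weight_missing: float = 0.3
    noise_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.base_adr_logit = np.asarray(self.base_adr_logit, dtype=float)
        self.drug_effect = np.asarray(self.drug_effect, dtype=float)
        self.gender_effect = np.asarray(self.gender_effect, dtype=float)
        self.age_effect = np.asarray(self.age_effect, dtype=float)
        if min(self.n_patients, self.n_diseases, self.n_drugs, self.n_adrs) < 1:
            raise ValueError("all entity counts must be >= 1")
        for p in (self.p_female, self.extra_drug_prob, self.noise_rate,
                  self.p_weight_missing):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.base_adr_logit.shape != (self.n_adrs,):
            raise ValueError("base_adr_logit must have shape (n_adrs,)")
        if self.drug_effect.shape != (self.n_drugs, self.n_adrs):
            raise ValueError("drug_effect must have shape (n_drugs, n_adrs)")
        if self.gender_effect.shape != (self.n_adrs,):
            raise ValueError("gender_effect must have shape (n_adrs,)")
        if self.age_effect.shape != (self.n_adrs, 3):
            raise ValueError("age_effect must have shape (n_adrs, 3)")

    # entity ID vocabularies (deterministic, zero-padded)
    def disease_ids(self) -> list[str]:
        w = len(str(self.n_diseases))
        return [f"D{i:0{w}d}" for i in range(self.n_diseases)]

    def drug_ids(self) -> list[str]:
        w = len(str(self.n_drugs))
        return [f"M{i:0{w}d}" for i in range(self.n_drugs)]

    def adr_ids(self) -> list[str]:
        w = len(str(self.n_adrs))
        return [f"S{i:0{w}d}" for i in range(self.n_adrs)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted nonzero effects of a generated cohort, for recovery scoring."""

    causal_pairs: frozenset[tuple[str, str]]    # (drug ID, ADR ID)
    gender_related_adrs: frozenset[str]
    age_related_adrs: frozenset[str]
    drug_effect_sizes: dict = field(default_factory=dict)
    gender_effect_sizes: dict = field(default_factory=dict)
    age_effect_sizes: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "causal_pairs": sorted(map(list, self.causal_pairs)),
            "gender_related_adrs": sorted(self.gender_related_adrs),
            "age_related_adrs": sorted(self.age_related_adrs),
            "drug_effect_sizes": {f"{m}|{s}": v for (m, s), v
                                  in sorted(self.drug_effect_sizes.items())},
            "gender_effect_sizes": dict(sorted(self.gender_effect_sizes.items())),
            "age_effect_sizes": {k: list(v) for k, v
                                 in sorted(self.age_effect_sizes.items())},
        }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[AdverseEventReport], GroundTruth]:
    """Sample a cohort of ``spec.n_patients`` retained reports.

    Deterministic for a fixed ``spec.seed``. The disease→drug candidate
    menus are drawn from a seed-derived stream before patient sampling,
    so they are a fixed property of the spec's world.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    world_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))

    disease_ids = spec.disease_ids()
    drug_ids = spec.drug_ids()
    adr_ids = spec.adr_ids()

    dis_pop = _zipf_weights(spec.n_diseases, spec.zipf_exponent)
    drug_pop = _zipf_weights(spec.n_drugs, spec.zipf_exponent)

    # each disease indicates a small menu of plausible drugs
    k = min(spec.candidates_per_disease, spec.n_drugs)
    menus = np.empty((spec.n_diseases, k), dtype=np.intp)
    for d in range(spec.n_diseases):
        menus[d] = world_rng.choice(spec.n_drugs, size=k, replace=False, p=drug_pop)

    mix_w = np.array([c[0] for c in spec.age_mixture])
    mix_w = mix_w / mix_w.sum()

    reports: list[AdverseEventReport] = []
    attempts = 0
    max_attempts = max(200 * spec.n_patients, 10_000)
    while len(reports) < spec.n_patients:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "resampling budget exhausted: the spec yields almost no "
                "reports with at least one ADR")
        sex = 2 if rng.random() < spec.p_female else 1
        comp = rng.choice(len(spec.age_mixture), p=mix_w)
        _, mu, sd = spec.age_mixture[comp]
        age = int(np.clip(round(rng.normal(mu, sd)), 0, 100))

        n_dis = 1 + rng.poisson(spec.diseases_per_patient_rate)
        n_dis = min(n_dis, spec.n_diseases)
        dis_idx = rng.choice(spec.n_diseases, size=n_dis, replace=False, p=dis_pop)

        drug_idx: set[int] = set()
        for d in dis_idx:
            n_dr = 1 + (rng.random() < spec.extra_drug_prob)
            n_dr = min(n_dr, k)
            drug_idx.update(rng.choice(menus[d], size=n_dr, replace=False))
        drug_arr = np.fromiter(drug_idx, dtype=np.intp)

        logits = (spec.base_adr_logit
                  + spec.drug_effect[drug_arr].sum(axis=0)
                  + (spec.gender_effect if sex == 2 else 0.0)
                  + spec.age_effect[:, age_group(age)])
        present = rng.random(spec.n_adrs) < _sigmoid(logits)
        if spec.noise_rate > 0:
            present |= rng.random(spec.n_adrs) < spec.noise_rate
        if not present.any():
            continue  # discard and resample: a report always has an event

        missing_w = rng.random() < spec.p_weight_missing
        weight = None if missing_w else round(
            float(np.clip(rng.normal(spec.weight_mean, spec.weight_sd), 30, 200)), 1)
        qual = int(rng.choice(5, p=[0.3, 0.2, 0.2, 0.1, 0.2])) + 1
        day = int(rng.integers(0, 3650))
        year, rem = 2013 + day // 365, day % 365
        month, dom = 1 + rem // 31, 1 + rem % 28
        reports.append(AdverseEventReport(
            report_id=f"R{len(reports):07d}",
            diseases=frozenset(disease_ids[i] for i in dis_idx),
            drugs=frozenset(drug_ids[i] for i in drug_arr),
            age=age, sex=sex, weight=weight, qualification=qual,
            date=f"{year:04d}-{month:02d}-{dom:02d}",
            adrs=frozenset(a for a, p in zip(adr_ids, present) if p),
        ))

    mi, si = np.nonzero(spec.drug_effect)
    causal = {(drug_ids[m], adr_ids[s]) for m, s in zip(mi, si)}
    gset = {adr_ids[s] for s in np.nonzero(spec.gender_effect)[0]}
    aset = {adr_ids[s] for s in np.nonzero(np.any(spec.age_effect != 0, axis=1))[0]}
    truth = GroundTruth(
        causal_pairs=frozenset(causal),
        gender_related_adrs=frozenset(gset),
        age_related_adrs=frozenset(aset),
        drug_effect_sizes={(drug_ids[m], adr_ids[s]): float(spec.drug_effect[m, s])
                           for m, s in zip(mi, si)},
        gender_effect_sizes={adr_ids[s]: float(spec.gender_effect[s])
                             for s in np.nonzero(spec.gender_effect)[0]},
        age_effect_sizes={adr_ids[s]: tuple(map(float, spec.age_effect[s]))
                          for s in
                          np.nonzero(np.any(spec.age_effect != 0, axis=1))[0]},
    )
    return reports, truth


def please_like_spec(scale: float = 0.02, seed: int = 12345,
                     gender_or: float = 3.0, age_or: float = 3.0,
                     drug_log_or: float = 2.0, gender_frac: float = 0.10,
                     age_frac: float = 0.15) -> CohortSpec:
    """A cohort spec whose dimensions are the full FAERS-derived cohort's
    scaled by ``scale`` (each count at least 10).

    Planted structure, drawn from the fixed ``seed``:

    * every ADR gets three causal drugs (popularity-weighted, so the
      planted pairs have exposure support) with log-odds increment
      ``drug_log_or`` (odds ratio ≈ 7.4 at the default),
    * a ``gender_frac`` share of ADRs is gender-related (|OR| =
      ``gender_or``, random sign),
    * an ``age_frac`` share is age-related (elderly OR = ``age_or``,
      child OR = sqrt of that, relative to adults),
    * baseline per-ADR prevalence is rank-skewed between roughly 0.5%
      and 12%.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    n_patients = max(10, math.ceil(scale * FULL_N_REPORTS))
    n_adrs = max(10, math.ceil(scale * FULL_N_ADRS))
    n_diseases = max(10, math.ceil(scale * FULL_N_DISEASES))
    n_drugs = max(10, math.ceil(scale * FULL_N_DRUGS))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    prevalence = 0.005 + 0.115 * np.arange(1, n_adrs + 1, dtype=float) ** -1.2
    base_logit = np.log(prevalence / (1 - prevalence))

    # causal drugs are drawn popularity-weighted: reporting databases are
    # dominated by signals on commonly used drugs, and min-count curation
    # guarantees every retained drug has substantial exposure
    drug_pop = _zipf_weights(n_drugs, 1.2)
    drug_effect = np.zeros((n_drugs, n_adrs))
    for s in range(n_adrs):
        for m in rng.choice(n_drugs, size=min(3, n_drugs), replace=False,
                            p=drug_pop):
            drug_effect[m, s] = drug_log_or

    gender_effect = np.zeros(n_adrs)
    g_idx = rng.choice(n_adrs, size=max(1, round(gender_frac * n_adrs)),
                       replace=False)
    gender_effect[g_idx] = rng.choice([-1.0, 1.0], size=g_idx.size) * np.log(gender_or)

    age_effect = np.zeros((n_adrs, 3))
    a_idx = rng.choice(n_adrs, size=max(1, round(age_frac * n_adrs)),
                       replace=False)
    signs = rng.choice([-1.0, 1.0], size=a_idx.size)
    age_effect[a_idx, 2] = signs * np.log(age_or)
    age_effect[a_idx, 0] = signs * 0.5 * np.log(age_or)

    return CohortSpec(
        n_patients=n_patients, n_diseases=n_diseases, n_drugs=n_drugs,
        n_adrs=n_adrs, base_adr_logit=base_logit, drug_effect=drug_effect,
        gender_effect=gender_effect, age_effect=age_effect, seed=seed,
    )
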