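"""Synthetic family-cohort generator (gene dropping).

Generates multi-generation pedigrees and polygenic phenotypes with exactly
the covariance structure the variance-components model assumes:
additive genetic values are gene-dropped down the pedigree (founders drawn
N(0, sigma2_a); each child gets the parental midpoint plus Mendelian
segregation noise N(0, sigma2_a/2 * (1 - (F_f + F_m)/2))), iid environmental
noise N(0, sigma2_e) is added, and fixed covariate effects (age, sex,
residence zone) with configurable coefficients are superimposed. The latent
value is affinely mapped to the questionnaire scale (centered on the target
cohort mean, optionally rounded and clipped to [16, 86] to emulate the
instrument's floor/ceiling).

Default demographics emulate a mid-size interior-Brazil family cohort:
~112 families totalling ~825 adults, age 46.4 +/- 16.3 truncated to [18, 89],
60.2% female, ~11.6% rural residence, cohort score mean 63.5 and SD ~11.2.
Ages are drawn iid per individual (not structured by generation) so that
covariate-variance arithmetic is exact; a generational-age mode adds realism
when wanted.

The module also houses two simulation oracles used to cross-check the
deterministic code paths: an allele-dropping Monte-Carlo estimate of the
relationship matrix, and vectorized gene-dropped additive values whose
empirical covariance estimates 2*Phi*sigma2_a.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meq import MEQItem, load_instrument
from .pedigree import Individual, Pedigree, RelationshipMatrix, Sex, kinship

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "SimulationError",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_cohort",
    "calibrated_config",
    "truncated_age_variance",
    "gene_drop_relationship",
    "gene_drop_values",
    "responses_for_total",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters; the seed fully determines the output.

    Variances are in (score units)^2 on the latent scale; covariate effects
    in score units (per year for age). ``mate_prob`` is the probability that
    a non-final-generation offspring marries in (bringing an unrelated
    founder spouse) and reproduces.
    """

    n_families: int = 112
    generations: int = 3
    mean_sibship: float = 2.0
    mate_prob: float = 0.22
    sigma2_a: float = 49.4
    sigma2_e: float = 53.5
    beta_age: float = 0.26
    beta_sex: float = 1.8  # male minus female
    beta_residence: float = 7.6  # rural minus municipal
    age_mean: float = 46.4
    age_sd: float = 16.3
    age_min: float = 18.0
    age_max: float = 89.0
    prop_female: float = 0.602
    prop_rural: float = 96.0 / 825.0
    mean_score: float = 63.5
    floor: int = 16
    ceiling: int = 86
    censor: bool = True
    generational_ages: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.generations < 2:
            raise SimulationError("need n_families >= 1 and generations >= 2")
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise SimulationError("variances must be nonnegative")
        if self.mean_sibship < 0 or not (0 <= self.mate_prob <= 1):
            raise SimulationError("degenerate family-shape parameters")
        for frac in (self.prop_female, self.prop_rural):
            if not (0 <= frac <= 1):
                raise SimulationError("fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """A simulated pedigree + phenotype table + generative truth echo."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.write(out / "pedigree.ped")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False, float_format="%.10g")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Simulate disconnected families: founder couples, sibships, in-marrying.

    Each family starts from a founder couple with Poisson(mean_sibship) + 1
    offspring; in each later generation every previous-generation offspring
    marries an unrelated founder with probability ``mate_prob`` and has
    Poisson(mean_sibship) + 1 children. Deterministic given the seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    individuals: list[Individual] = []
    for f in range(1, config.n_families + 1):
        fam = f"F{f:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}-{counter:03d}"

        def founder(sex: Sex) -> Individual:
            ind = Individual(new_id(), fam, None, None, sex)
            individuals.append(ind)
            return ind

        def child_of(father: Individual, mother: Individual) -> Individual:
            sex = Sex.female if rng.random() < config.prop_female else Sex.male
            ind = Individual(new_id(), fam, father.id, mother.id, sex)
            individuals.append(ind)
            return ind

        def sibship(father: Individual, mother: Individual) -> list[Individual]:
            k = int(rng.poisson(config.mean_sibship)) + 1
            return [child_of(father, mother) for _ in range(k)]

        father = founder(Sex.male)
        mother = founder(Sex.female)
        current = sibship(father, mother)
        for _ in range(config.generations - 2):
            nxt: list[Individual] = []
            for person in current:
                if rng.random() >= config.mate_prob:
                    continue
                spouse = founder(Sex.male if person.sex is Sex.female else Sex.female)
                dad, mom = (person, spouse) if person.sex is Sex.male else (spouse, person)
                nxt.extend(sibship(dad, mom))
            current = nxt
    return Pedigree(individuals)


def _inbreeding(A: RelationshipMatrix) -> np.ndarray:
    """Per-individual inbreeding coefficients from the matrix diagonal."""
    return np.diag(A.values) - 1.0


def gene_drop_values(
    ped: Pedigree,
    sigma2_a: float,
    n_reps: int,
    rng: np.random.Generator,
    A: RelationshipMatrix | None = None,
) -> np.ndarray:
    """Vectorized gene dropping of additive values: (n_reps, n) array.

    Founders draw N(0, sigma2_a); children get the parental midpoint plus
    segregation noise with the inbreeding-adjusted variance
    sigma2_a/2 * (1 - (F_father + F_mother)/2). A parent missing from the
    pedigree is a phantom unrelated founder drawn on the fly. Under the
    infinitesimal model the resulting covariance is exactly 2*Phi*sigma2_a.
    """
    n = len(ped)
    if A is None:
        A = kinship(ped)
    F = _inbreeding(A)
    sd_f = np.sqrt(sigma2_a)
    out = np.empty((n_reps, n))
    order = ped.topological_order()
    for pos in order:
        ind = ped.individuals[pos]
        fi = ped.index.get(ind.father_id) if ind.father_id else None
        mi = ped.index.get(ind.mother_id) if ind.mother_id else None
        if fi is None and mi is None:
            out[:, pos] = rng.normal(0.0, sd_f, size=n_reps)
            continue
        a_f = out[:, fi] if fi is not None else rng.normal(0.0, sd_f, size=n_reps)
        a_m = out[:, mi] if mi is not None else rng.normal(0.0, sd_f, size=n_reps)
        Ff = F[fi] if fi is not None else 0.0
        Fm = F[mi] if mi is not None else 0.0
        seg_var = 0.5 * sigma2_a * (1.0 - 0.5 * (Ff + Fm))
        out[:, pos] = 0.5 * (a_f + a_m) + rng.normal(
            0.0, np.sqrt(seg_var), size=n_reps
        )
    return out


def truncated_age_variance(config: SimConfig) -> float:
    """Analytic variance of the truncated-normal age distribution."""
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    return float(stats.truncnorm.var(a, b, loc=config.age_mean, scale=config.age_sd))


def simulate_phenotypes(
    ped: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    A: RelationshipMatrix | None = None,
) -> SyntheticCohort:
    """Gene-drop one phenotype vector plus covariates over a pedigree."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(ped)
    if A is None:
        A = kinship(ped)
    g = gene_drop_values(ped, config.sigma2_a, 1, rng, A=A)[0]
    e = rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)

    a_std = (config.age_min - config.age_mean) / config.age_sd
    b_std = (config.age_max - config.age_mean) / config.age_sd
    if config.generational_ages:
        # invented realism mode: founders oldest, each later generation ~27y
        # younger, jittered; truncated to the eligible range
        depth = np.zeros(n)
        for pos in ped.topological_order():
            ind = ped.individuals[pos]
            parents = [p for p in (ind.father_id, ind.mother_id) if p]
            if parents:
                depth[pos] = max(depth[ped.index[p]] for p in parents) + 1.0
        base = config.age_mean + (depth.max() / 2.0 - depth) * 27.0
        age = np.clip(
            base + rng.normal(0.0, 8.0, size=n), config.age_min, config.age_max
        )
    else:
        age = stats.truncnorm.rvs(
            a_std, b_std, loc=config.age_mean, scale=config.age_sd,
            size=n, random_state=rng,
        )
    female = rng.random(n) < config.prop_female
    rural = rng.random(n) < config.prop_rural
    male01 = (~female).astype(float)
    rural01 = rural.astype(float)

    cov_part = (
        config.beta_age * age + config.beta_sex * male01 + config.beta_residence * rural01
    )
    # center so the cohort mean sits at mean_score in expectation
    exp_cov = (
        config.beta_age * float(stats.truncnorm.mean(
            a_std, b_std, loc=config.age_mean, scale=config.age_sd))
        + config.beta_sex * (1.0 - config.prop_female)
        + config.beta_residence * config.prop_rural
    )
    latent = config.mean_score - exp_cov + g + e + cov_part
    if config.censor:
        meq_total = np.clip(np.round(latent), config.floor, config.ceiling).astype(int)
    else:
        meq_total = latent

    phen = pd.DataFrame(
        {
            "individual_id": ped.ids,
            "family_id": [ind.family_id for ind in ped.individuals],
            "meq_total": meq_total,
            "latent_value": latent,
            "sex": np.where(female, "female", "male"),
            "age": np.round(age, 6),
            "residence": np.where(rural, "rural", "municipal"),
        }
    )
    var_g = float(np.var(g, ddof=1))
    var_e = float(np.var(e, ddof=1))
    var_cov = float(np.var(cov_part, ddof=1))
    truth = {
        "config": config.to_dict(),
        "n_individuals": n,
        "realized": {
            "var_additive": var_g,
            "var_environment": var_e,
            "var_covariates": var_cov,
            "h2_residual": var_g / (var_g + var_e) if var_g + var_e > 0 else float("nan"),
            "h2_marginal": var_g / (var_g + var_e + var_cov)
            if var_g + var_e + var_cov > 0
            else float("nan"),
        },
    }
    return SyntheticCohort(pedigree=ped, phenotypes=phen, truth=truth)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Pedigree + phenotypes from one seed (single rng stream)."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    return simulate_phenotypes(ped, config, rng)


def calibrated_config(
    h2_adjusted: float,
    h2_unadjusted: float,
    n_families: int = 112,
    seed: int = 0,
    age_share: float = 0.95,
) -> SimConfig:
    """Generator settings that realize two target heritability readings.

    On a unit residual scale (sigma2_a + sigma2_e = 1) the additive fraction
    equals ``h2_adjusted``; independent covariate effects of total variance
    sigma2_cov then dilute the covariate-free estimate by the
    variance-inflation identity

        h2_unadjusted = sigma2_a / (1 + sigma2_cov)
        => sigma2_cov = h2_adjusted / h2_unadjusted - 1.

    The covariate variance is split between age (``age_share``) and sex,
    matching the dominance of the age trend over the sex difference seen in
    adult cohorts; betas are solved from the analytic covariate variances.
    Censoring is off: the calibration is about the latent model, and h2 is
    invariant to the affine scale mapping anyway.
    """
    if not (0 < h2_unadjusted <= h2_adjusted < 1):
        raise SimulationError("need 0 < h2_unadjusted <= h2_adjusted < 1")
    sigma2_cov = h2_adjusted / h2_unadjusted - 1.0
    base = SimConfig()
    var_age = truncated_age_variance(base)
    var_sex = base.prop_female * (1.0 - base.prop_female)
    beta_age = float(np.sqrt(age_share * sigma2_cov / var_age))
    beta_sex = float(np.sqrt((1.0 - age_share) * sigma2_cov / var_sex))
    return dataclasses.replace(
        base,
        n_families=n_families,
        sigma2_a=h2_adjusted,
        sigma2_e=1.0 - h2_adjusted,
        beta_age=beta_age,
        beta_sex=beta_sex,
        beta_residence=0.0,
        mean_score=0.0,
        censor=False,
        seed=seed,
    )


def gene_drop_relationship(
    ped: Pedigree, n_reps: int = 100_000, rng: np.random.Generator | None = None
) -> tuple[RelationshipMatrix, np.ndarray]:
    """Monte-Carlo oracle for 2*Phi by discrete allele dropping.

    Each replicate assigns every founder two unique allele labels and drops
    them with independent Mendelian picks. For i != j the per-replicate
    statistic is half the count of identical (allele of i, allele of j)
    pairs over the 4 combinations (so its mean estimates 2*phi); the
    diagonal statistic is 1 + [i's two alleles identical] (mean 1 + F).
    Returns the estimate and a matching matrix of Monte-Carlo standard
    errors. Independent of the tabular recursion.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(ped)
    order = ped.topological_order()
    alleles = np.empty((n, 2, n_reps), dtype=np.int32)
    next_label = 0
    phantom: dict[tuple[str, int], int] = {}
    for pos in order:
        ind = ped.individuals[pos]
        for slot, pid in enumerate((ind.father_id, ind.mother_id)):
            if pid is None:
                # allele from a (phantom) unrelated founder parent, which
                # holds two unique labels and transmits one at random
                alleles[pos, slot, :] = 2 * next_label + (
                    rng.random(n_reps) < 0.5
                )
                next_label += 1
            else:
                ppos = ped.index[pid]
                pick = (rng.random(n_reps) < 0.5).astype(np.int8)
                alleles[pos, slot, :] = alleles[ppos, 0, :] * (pick == 0) + alleles[
                    ppos, 1, :
                ] * (pick == 1)
    est = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        same = (alleles[i, 0] == alleles[i, 1]).astype(float)
        stat = 1.0 + same
        est[i, i] = stat.mean()
        se[i, i] = stat.std(ddof=1) / np.sqrt(n_reps)
        for j in range(i):
            match = np.zeros(n_reps)
            for a in range(2):
                for b in range(2):
                    match += (alleles[i, a] == alleles[j, b]).astype(float)
            stat = 0.5 * match
            est[i, j] = est[j, i] = stat.mean()
            se[i, j] = se[j, i] = stat.std(ddof=1) / np.sqrt(n_reps)
    return RelationshipMatrix(ped.ids, est), se


def responses_for_total(
    total: int,
    instrument: Sequence[MEQItem] | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """A 19-vector of 1-based option indices summing to ``total``.

    Greedy allocator: start every item at its minimum-score option and raise
    item scores (largest feasible increment first, randomized ties) until
    the deficit is closed. Any allocation achieving the target is valid; used
    to exercise end-to-end scoring on synthetic cohorts.
    """
    if instrument is None:
        instrument = load_instrument()
    if rng is None:
        rng = np.random.default_rng(0)
    lo = sum(it.min_score for it in instrument)
    hi = sum(it.max_score for it in instrument)
    if not (lo <= total <= hi):
        raise SimulationError(f"target total {total} outside [{lo}, {hi}]")
    # per item: current score and the sorted ladder of attainable scores
    ladders = [sorted(set(it.option_scores)) for it in instrument]
    current = [lad[0] for lad in ladders]
    deficit = total - sum(current)
    while deficit > 0:
        candidates = []  # (increment, item position, new score)
        for k, (lad, cur) in enumerate(zip(ladders, current)):
            for s in lad:
                if cur < s <= cur + deficit:
                    candidates.append((s - cur, k, s))
        if not candidates:
            raise SimulationError("allocator stuck; instrument has no unit steps")
        best = max(c[0] for c in candidates)
        pool = [c for c in candidates if c[0] == best]
        inc, k, s = pool[int(rng.integers(len(pool)))]
        current[k] = s
        deficit -= inc
    responses = []
    for it, want in zip(instrument, current):
        opts = [k + 1 for k, s in enumerate(it.option_scores) if s == want]
        responses.append(opts[int(rng.integers(len(opts)))])
    return responses
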