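import numpy as np
import pytest
from hypothesis import settings

import meqherit as mh
from meqherit.pedigree import Individual, Pedigree, Sex

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def ind(iid, fam, father, mother, sex):
    return Individual(iid, fam, father, mother, Sex(sex))


@pytest.fixture(scope="session")
def instrument():
    return mh.load_instrument()


@pytest.fixture(scope="session")
def extended_pedigree():
    """Two grandparents, two sibs who marry in, their kids (first cousins)."""
    return Pedigree(
        [
            ind("gp1", "F1", None, None, "male"),
            ind("gm1", "F1", None, None, "female"),
            ind("p1", "F1", "gp1", "gm1", "male"),
            ind("p2", "F1", "gp1", "gm1", "female"),
            ind("sp1", "F1", None, None, "female"),
            ind("sp2", "F1", None, None, "male"),
            ind("c1", "F1", "p1", "sp1", "male"),
            ind("c2", "F1", "sp2", "p2", "female"),
            ind("gc1", "F1", None, None, "female"),
            ind("hs1", "F1", "p1", "gc1", "male"),  # half sib of c1
        ]
    )


@pytest.fixture(scope="session")
def inbred_pedigree():
    """Two sibships intermarry -> double first cousins -> inbred offspring."""
    return Pedigree(
        [
            ind("a", "F1", None, None, "male"),
            ind("b", "F1", None, None, "female"),
            ind("c", "F1", None, None, "male"),
            ind("d", "F1", None, None, "female"),
            ind("s1a", "F1", "a", "b", "male"),
            ind("s1b", "F1", "a", "b", "female"),
            ind("s2a", "F1", "c", "d", "male"),
            ind("s2b", "F1", "c", "d", "female"),
            ind("x", "F1", "s1a", "s2b", "male"),
            ind("y", "F1", "s2a", "s1b", "female"),
            ind("z", "F1", "x", "y", "male"),
        ]
    )


@pytest.fixture(scope="session")
def cousin_offspring_pedigree():
    """Offspring of (single) first cousins: F = 1/16."""
    return Pedigree(
        [
            ind("gp", "F1", None, None, "male"),
            ind("gm", "F1", None, None, "female"),
            ind("u1", "F1", "gp", "gm", "male"),
            ind("u2", "F1", "gp", "gm", "female"),
            ind("w1", "F1", None, None, "female"),
            ind("w2", "F1", None, None, "male"),
            ind("k1", "F1", "u1", "w1", "male"),
            ind("k2", "F1", "w2", "u2", "female"),
            ind("q", "F1", "k1", "k2", "female"),
        ]
    )


@pytest.fixture(scope="session")
def fixture30():
    """A 30-individual, 5-family uncensored cohort used as the ML fit fixture."""
    cfg = mh.SimConfig(n_families=5, seed=42, censor=False)
    coh = mh.simulate_cohort(cfg)
    assert len(coh.pedigree) == 30
    return coh


@pytest.fixture(scope="session")
def calibrated_batch():
    """100 replicate cohorts at the calibrated two-level heritability design.

    Generates cohorts whose adjusted-model additive fraction is 0.48 and
    whose independent covariate effects dilute the covariate-free estimate
    to 0.21, then fits the unadjusted, sex+age, and sex+age+age^2+sex*age
    models on each. Shared across recovery and acceptance tests.
    """
    models = [m for m in mh.TABLE2_MODELS if m.name != "sex_age_residence"]
    rows = {"unadjusted": [], "sex_age": [], "sex_age_age2_sexage": [], "se_sex_age": []}
    seeds = np.random.default_rng(20240101).integers(2**31, size=100)
    for s in seeds:
        cfg = mh.calibrated_config(0.48, 0.21, seed=int(s))
        coh = mh.simulate_cohort(cfg)
        phen = coh.phenotypes.assign(meq_total=coh.phenotypes["latent_value"])
        fits = mh.fit_table2_suite(phen, coh.pedigree, models=models)
        for f in fits:
            rows[f.model].append(f.h2)
        rows["se_sex_age"].append([f for f in fits if f.model == "sex_age"][0].se_h2)
    return {k: np.array(v) for k, v in rows.items()}
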