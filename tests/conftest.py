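import numpy as np
import pytest

from trophostab import (
    FoodWebModel,
    Group,
    generate_ensemble,
    solve_mass_balance,
)


def make_pair_web(ee_producer=None, b_producer=10.0):
    """Producer (B=10, P/B=2) eaten exclusively by one consumer
    (B=1, Q/B=5, P/B=1); the producer's EE (or biomass) is left unknown."""
    groups = [
        Group("prod", biomass=b_producer, pb=2.0, qb=0.0, ee=ee_producer),
        Group("cons", biomass=1.0, pb=1.0, qb=5.0, ee=0.0),
    ]
    diet = np.array([[0.0, 1.0], [0.0, 0.0]])
    return FoodWebModel(groups, diet, "bay", "pair")


def make_chain3():
    """Producer -> herbivore -> predator chain plus an omnivore-friendly
    topology used by trophic-level examples."""
    groups = [
        Group("prod", biomass=100.0, pb=10.0, qb=0.0, ee=None),
        Group("herb", biomass=10.0, pb=2.0, qb=10.0, ee=None),
        Group("pred", biomass=1.0, pb=0.5, qb=2.5, ee=None),
    ]
    diet = np.zeros((3, 3))
    diet[0, 1] = 1.0  # herbivore eats the producer
    diet[1, 2] = 1.0  # predator eats the herbivore
    return FoodWebModel(groups, diet, "estuary", "chain3")


def make_omnivore_web():
    """Producer, herbivore, and an omnivore splitting its diet 50/50
    between producer and herbivore (trophic level 2.5)."""
    groups = [
        Group("prod", biomass=100.0, pb=10.0, qb=0.0, ee=None),
        Group("herb", biomass=10.0, pb=2.0, qb=10.0, ee=None),
        Group("omni", biomass=1.0, pb=0.5, qb=2.5, ee=None),
    ]
    diet = np.zeros((3, 3))
    diet[0, 1] = 1.0
    diet[0, 2] = 0.5
    diet[1, 2] = 0.5
    return FoodWebModel(groups, diet, "estuary", "omni3")


@pytest.fixture()
def pair_web():
    return make_pair_web()


@pytest.fixture()
def balanced_pair():
    return solve_mass_balance(make_pair_web())


@pytest.fixture()
def balanced_chain():
    return solve_mass_balance(make_chain3())


@pytest.fixture(scope="session")
def ensemble12():
    """Small reusable ensemble spanning the generator's study conditions."""
    return generate_ensemble(12, seed=42)
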