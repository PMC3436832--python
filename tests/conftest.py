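import numpy as np
import pytest

from gobayes.annotations import AnnotationTable
from gobayes.model import GOActivityModel
from gobayes.simulate import make_four_term_scenario
from gobayes.types import PriorSpec


@pytest.fixture(scope="session")
def four_term():
    return make_four_term_scenario()


@pytest.fixture(scope="session")
def four_term_table(four_term):
    table = AnnotationTable()
    for term in four_term.terms:
        for g in term.gene_ids:
            table.add(term.term_id, g)
    return table


@pytest.fixture()
def four_term_model(four_term):
    return GOActivityModel.from_probabilities(four_term.term_probs)


def random_small_instance(rng, epsilon=0.5, max_terms=3, max_slots=12):
    """A random instance small enough for exact enumeration."""
    priors = PriorSpec.uniform(epsilon)
    K = int(rng.integers(1, max_terms + 1))
    gammas = rng.integers(1, 5, size=K)
    while gammas.sum() > max_slots:
        gammas = rng.integers(1, 5, size=K)
    probs = {
        f"T{k}": rng.uniform(0.02, 0.98, size=int(g)).tolist()
        for k, g in enumerate(gammas)
    }
    return GOActivityModel.from_probabilities(probs, priors=priors), priors
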