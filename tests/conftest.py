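import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


def random_alignment(rng, n, L, missing_frac=0.0, alphabet="ACGT"):
    """Random alignment as a list of strings; optional gap/N contamination."""
    mat = rng.choice(list(alphabet), size=(n, L))
    if missing_frac > 0:
        mask = rng.random((n, L)) < missing_frac
        missing = rng.choice(["-", "N", "R"], size=(n, L))
        mat = np.where(mask, missing, mat)
    return ["".join(row) for row in mat]


def oracle_p_distance(a, b):
    """Literal per-column p-distance with pairwise deletion."""
    diff = comp = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            comp += 1
            diff += x != y
    if comp == 0:
        raise ZeroDivisionError("no comparable sites")
    return diff / comp, comp


def oracle_apd(seqs):
    """Brute-force double-loop APD (percent)."""
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d, _ = oracle_p_distance(seqs[i], seqs[j])
            vals.append(d)
    return 100.0 * sum(vals) / len(vals)


def oracle_chisquare(obs, exp):
    """Textbook Pearson goodness-of-fit statistic."""
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


@pytest.fixture
def tiny_set():
    from barcodevar import AlignedSeqSet

    return AlignedSeqSet(
        names=["a", "b", "c"],
        seqs=["AAAA", "AAAT", "AATT"],
        groups={"a": "g1", "b": "g1", "c": "g1"},
    )


@pytest.fixture(scope="session")
def human_like_sim():
    """One cached human-like simulation shared by read-only tests."""
    from barcodevar import synth

    return synth.simulate_set(synth.preset("human-like", n=60, seed=101))


@pytest.fixture(scope="session")
def chimp_like_sim():
    from barcodevar import synth

    return synth.simulate_set(synth.preset("chimp-like", n=60, seed=202))
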