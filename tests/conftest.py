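import numpy as np
import pytest

from foldkspec import seqio, spectrum, synthetic


@pytest.fixture(scope="session")
def space3():
    return spectrum.feature_space(3)


@pytest.fixture(scope="session")
def space6():
    return spectrum.feature_space(6)


@pytest.fixture(scope="session")
def gapped_dataset():
    """Small planted-gapped-motif dataset: 30 positives, 400 bp, 4 scrambles."""
    spec = synthetic.PlantSpec(consensus="GTNNAC", plants_per_sequence=3, seed=11)
    return synthetic.make_dataset(spec, n_pos=30, length=400, n_scrambles=4, seed=11)


@pytest.fixture(scope="session")
def gapped_design(gapped_dataset, space6):
    """Featurized design matrix and labels for the small gapped dataset."""
    bg = seqio.build_background(gapped_dataset.sequences, 6, pseudocount=1.0)
    X = spectrum.featurize_matrix(gapped_dataset.sequences, space6, bg)
    y = np.array([s.label for s in gapped_dataset.sequences], dtype=float)
    return {"X": X, "y": y, "bg": bg, "dataset": gapped_dataset}


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


def oracle_gapped_count(residues, pattern):
    """Brute-force sliding-window wildcard matcher (test oracle).

    N in the pattern matches any base; windows containing N in the sequence
    never match.
    """
    k = len(pattern)
    count = 0
    for i in range(len(residues) - k + 1):
        window = residues[i : i + k]
        if "N" in window:
            continue
        if all(p == "N" or p == w for p, w in zip(pattern, window)):
            count += 1
    return count
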