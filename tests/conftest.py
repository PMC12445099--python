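import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rrnppminer import pipeline, profile_hmm, synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

#: corpus seed used across the suite (one fixed realization of the
#: generator's default study conditions)
CORPUS_SEED = 1


@pytest.fixture(scope="session")
def default_corpus():
    """Default-scale synthetic corpus: 20 genomes x 200 kbp, 5 clusters."""
    return sd.generate_corpus(sd.SyntheticConfig(rng_seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def default_result(default_corpus):
    genomes, _manifest, baits, seeds = default_corpus
    return pipeline.run_pipeline(genomes, baits, seeds, calibration_seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def small_corpus():
    """A 5-genome, 50-kbp corpus for cheaper per-module tests."""
    cfg = sd.SyntheticConfig(
        rng_seed=5,
        genome_length=50_000,
        n_genomes_per_species={
            "Streptococcus thermophilus": 2,
            "Streptococcus salivarius": 2,
            "Streptococcus vestibularis": 1,
        },
    )
    return sd.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_result(small_corpus):
    genomes, _manifest, baits, seeds = small_corpus
    return pipeline.run_pipeline(genomes, baits, seeds, calibration_seed=7)


@pytest.fixture(scope="session")
def mini_profile():
    """A small calibrated profile (33 baits of length 60) for search tests."""
    rng = np.random.default_rng(11)
    ancestor = sd.random_protein(60, rng)
    rows = []
    for fam, sub, count in [("Rgg", "SHP/Rgg", 20), ("ComR", "ComS/ComR", 13)]:
        proto, _ = sd.mutate_protein(ancestor, 0.6, rng)
        for i in range(count):
            seq, _ = sd.mutate_protein(proto, 0.7, rng)
            rows.append((f"{fam}{i}", fam, sub, seq))
    aln = profile_hmm.BaitAlignment(rows)
    prof = profile_hmm.build_profile(aln)
    calib = profile_hmm.calibrate_evalues(prof, n_random=500, seed=2, length_dist=120)
    return aln, prof, calib
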