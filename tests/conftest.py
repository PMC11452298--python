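import numpy as np
import pytest

from indelsplice.simulate import SimulationConfig, build_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """One default synthetic cohort shared across the suite."""
    out = tmp_path_factory.mktemp("cohort")
    return build_cohort(SimulationConfig(seed=42), out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_indels(rng, chrom_len, n, chrom="chrT", seq=None):
    """Random non-colliding raw indels for selection/liftover tests."""
    from indelsplice.variants import Indel

    out = []
    for _ in range(n):
        pos0 = int(rng.integers(0, chrom_len - 30))
        if rng.random() < 0.5:  # deletion
            span = int(rng.integers(2, 8))
            ref = (
                seq[pos0 : pos0 + span]
                if seq is not None
                else "".join(rng.choice(list("ACGT"), size=span))
            )
            alt = ref[0]
        else:  # insertion
            anchor = seq[pos0] if seq is not None else str(rng.choice(list("ACGT")))
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 12))))
            ref, alt = anchor, anchor + ins
        out.append(Indel(chrom, pos0 + 1, ref, alt))
    return out
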