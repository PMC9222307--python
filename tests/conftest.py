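
import pytest
from hypothesis import settings

from riskarch import combined_probability

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def iterative_solve(spec, n_max=100_000):
    """Independent brute-force oracle: step N upward until Pt <= threshold."""
    n = 0
    while combined_probability(spec, n) > spec.threshold:
        n += 1
        if n > n_max:
            raise AssertionError("iterative oracle exceeded n_max")
    return n


@pytest.fixture(scope="session")
def pgc_like_table():
    """Variant table mirroring the published list's composition: 128 variants,
    14 indels, balanced case/control directions, mean RAF 0.44."""
    from riskarch import VariantTableParams, gen_variant_table

    return gen_variant_table(VariantTableParams(seed=20220610))
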