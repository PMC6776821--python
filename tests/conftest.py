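import numpy as np
import pytest

from liabkin.relatedness import FULL_SISTER, MATERNAL_HALF_SISTER


def reconstructed_2x2(both_affected, both_unaffected, discordant):
    """Symmetric 2x2 pair table from a concordant/discordant summary."""
    return np.array(
        [
            [both_unaffected, discordant / 2.0],
            [discordant / 2.0, both_affected],
        ]
    )


@pytest.fixture(scope="session")
def adhd_pair_tables():
    """ADHD sister-pair tables reconstructed from the published register
    summary (full sisters and maternal half-sisters)."""
    return {
        FULL_SISTER: reconstructed_2x2(787, 322529, 11117),
        MATERNAL_HALF_SISTER: reconstructed_2x2(292, 52031, 4713),
    }


def random_correlation_matrix(rng, d):
    """Random full-rank correlation matrix."""
    A = rng.normal(size=(d, d + 2))
    S = A @ A.T
    sd = np.sqrt(np.diag(S))
    R = S / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    return R
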