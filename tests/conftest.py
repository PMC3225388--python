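import itertools

import numpy as np
import pytest
from scipy.special import expit

from collapsim import FixedEffectModel


@pytest.fixture(scope="session")
def figure1_model() -> FixedEffectModel:
    """The illustrative disease: K=1%, allelic OR 1.6, p_a=0.25, 100 risk SNPs."""
    return FixedEffectModel.from_or(0.01, 1.6, 0.25, 100)


def enumerate_joint(beta0: float, beta: float, p: float, m: int) -> np.ndarray:
    """Brute-force joint pmf P(Y=y, G=g) over all 2^m phased allele configs.

    Each of the m allele positions independently carries the risk allele with
    probability p; configurations are collapsed by total count.  Exponential
    in m — use only for m <= ~12.
    """
    joint = np.zeros((2, m + 1))
    for config in itertools.product((0, 1), repeat=m):
        g = sum(config)
        prob = p**g * (1 - p) ** (m - g)
        pen = expit(beta0 + beta * g)
        joint[0, g] += prob * (1 - pen)
        joint[1, g] += prob * pen
    return joint


def enumerate_focal_pmf(beta0: float, beta: float, p: float, m: int, y: int) -> np.ndarray:
    """Brute-force P(X=x | Y=y) with X the count on the first two allele slots."""
    w = np.zeros(3)
    for config in itertools.product((0, 1), repeat=m):
        x = config[0] + config[1]
        g = sum(config)
        prob = p**g * (1 - p) ** (m - g)
        pen = expit(beta0 + beta * g)
        w[x] += prob * (pen if y == 1 else 1 - pen)
    return w / w.sum()
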