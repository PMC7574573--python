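"""Independent brute-force oracles used by the HMM tests.

These enumerate all 2**T hidden-state sequences explicitly and never
touch the package's forward/Viterbi code paths.
"""

from itertools import product

import numpy as np
from scipy.special import logsumexp


def _path_logjoint(d, path, params):
    """log p(states, displacements) for one explicit state sequence;
    impossible transitions contribute -inf."""
    with np.errstate(divide="ignore"):
        lp = np.log(params.delta[path[0]])
        for i in range(1, len(path)):
            lp += np.log(params.A[path[i - 1], path[i]])
    for i, k in enumerate(path):
        prev, cur = d[i], d[i + 1]
        g, th, s = params.gamma[k], params.theta[k], params.sigma[k]
        mx = g * (np.cos(th) * prev[0] - np.sin(th) * prev[1])
        my = g * (np.sin(th) * prev[0] + np.cos(th) * prev[1])
        r2 = (cur[0] - mx) ** 2 + (cur[1] - my) ** 2
        lp += -np.log(2 * np.pi * s**2) - r2 / (2 * s**2)
    return lp


def brute_force_loglik(d, params):
    """Marginal log-likelihood by exhaustive enumeration (one segment)."""
    T = len(d) - 1
    lps = [_path_logjoint(d, path, params) for path in product([0, 1], repeat=T)]
    return float(logsumexp(lps))


def brute_force_viterbi(d, params):
    """Most probable state path by exhaustive argmax (one segment)."""
    T = len(d) - 1
    best, best_lp = None, -np.inf
    for path in product([0, 1], repeat=T):
        lp = _path_logjoint(d, path, params)
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def random_params(rng):
    from sealforage.hmm import HmmParams

    stay = rng.uniform(0.6, 0.95, 2)
    delta = rng.dirichlet([1, 1])
    return HmmParams(
        theta=rng.uniform(-np.pi, np.pi, 2),
        gamma=rng.uniform(0.1, 0.9, 2),
        sigma=rng.uniform(0.5, 3.0, 2),
        A=np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]]),
        delta=delta,
    )
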