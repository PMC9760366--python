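"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities by a different route than the
package (permutation resampling instead of multivariate-t quadrature) so
the two implementations check each other.
"""

import numpy as np


def _pooled_t_stats(arrays, control):
    """Per-comparison t statistics with the Dunnett pooled variance."""
    groups = list(arrays) + [control]
    ss = sum(((a - a.mean()) ** 2).sum() for a in groups)
    df = sum(a.size for a in groups) - len(groups)
    s2 = ss / df
    cmean = control.mean()
    return np.array([
        (a.mean() - cmean) / np.sqrt(s2 * (1 / a.size + 1 / control.size))
        for a in arrays
    ])


def maxt_adjusted_p(arrays, control, n_permutations=20_000, seed=0):
    """Permutation max-T adjusted p-values for many-to-one comparisons.

    Group labels (including the control's) are permuted; each
    comparison's adjusted p is the fraction of permutations whose maximal
    absolute t statistic reaches its observed absolute t.
    """
    arrays = [np.asarray(a, float) for a in arrays]
    control = np.asarray(control, float)
    t_obs = np.abs(_pooled_t_stats(arrays, control))
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays + [control])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(arrays))
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        bounds = np.cumsum([0] + sizes)
        parts = [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        ctrl = perm[bounds[-1]:]
        tmax = np.abs(_pooled_t_stats(parts, ctrl)).max()
        exceed += tmax >= t_obs - 1e-12
    return (1 + exceed) / (n_permutations + 1)
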