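"""Independent reference implementations used only as test oracles."""

import itertools
import math

import numpy as np
from scipy import ndimage

_CONN = {6: 1, 18: 2, 26: 3}


def tfce_reference(stat3d, mask, n_steps=100, E=0.5, H=2.0, connectivity=26,
                   voxel_volume=1.0, mass=False):
    """Literal TFCE: relabel the suprathreshold set at every height."""
    st = ndimage.generate_binary_structure(3, _CONN[connectivity])
    s = np.where(mask, stat3d, 0.0)
    hmax = s.max()
    out = np.zeros_like(s)
    if hmax <= 0:
        return out
    dh = hmax / n_steps
    for k in range(1, n_steps + 1):
        h = hmax * (k / n_steps)
        supra = s >= h
        lab, nl = ndimage.label(supra, structure=st)
        if nl == 0:
            continue
        if mass:
            support = ndimage.sum_labels(s - h, lab,
                                         index=np.arange(1, nl + 1))
            support = np.concatenate([[0.0], support * voxel_volume])[lab]
        else:
            sizes = np.bincount(lab.ravel(), minlength=nl + 1).astype(float)
            sizes[0] = 0.0
            support = (sizes * voxel_volume)[lab]
        out += np.where(supra, support ** E * h ** H * dh, 0.0)
    return out * mask


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every group labeling."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = a.size

    def u_stat(x, y):
        diff = x[:, None] - y[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_stat(a, b)
    mid = n_a * b.size / 2.0
    us = [u_stat(pooled[list(idx)],
                 np.delete(pooled, list(idx)))
          for idx in itertools.combinations(range(pooled.size), n_a)]
    us = np.asarray(us)
    # two-sided: double the smaller tail (distribution is symmetric about mid)
    tail = np.mean(us >= u_obs) if u_obs >= mid else np.mean(us <= u_obs)
    return u_obs, min(1.0, 2.0 * tail)


def perm_test_single_voxel(y, score):
    """|t|-based corrected p over all orderings of y against one regressor."""
    y, score = np.asarray(y, float), np.asarray(score, float)
    n = y.size

    def abs_t(yy):
        X = np.column_stack([np.ones(n), score])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        sigma2 = resid @ resid / (n - 2)
        c = np.linalg.inv(X.T @ X)[1, 1]
        return abs(beta[1]) / math.sqrt(sigma2 * c)

    t_obs = abs_t(y)
    ts = np.array([abs_t(y[list(p)])
                   for p in itertools.permutations(range(n))])
    return np.mean(ts >= t_obs - 1e-12)
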