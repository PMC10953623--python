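"""Independent brute-force implementations used as test oracles.

Deliberately written as plain Python loops over the algorithm
definitions, sharing no code with the package implementations.
"""

from __future__ import annotations

import numpy as np


def bruteforce_label_fusion(target, entries, candidate_mask, patch_radius,
                            search_radius, preselection_threshold,
                            bandwidth_floor, decision_threshold):
    """Triple-loop patch-based label fusion.

    ``entries`` is a list of (intensity array, label array).  Window
    centres outside the volume contribute no patch; patches straddling
    the boundary read zeros.  Returns (labels, votes).
    """
    T = np.asarray(target, dtype=np.float64)
    shape = T.shape
    pr, sr = patch_radius, search_radius
    C1 = (0.01 * 100.0) ** 2
    C2 = (0.03 * 100.0) ** 2

    def patch(arr, c):
        out = np.zeros((2 * pr + 1,) * 3)
        for di in range(-pr, pr + 1):
            for dj in range(-pr, pr + 1):
                for dk in range(-pr, pr + 1):
                    i, j, k = c[0] + di, c[1] + dj, c[2] + dk
                    if 0 <= i < shape[0] and 0 <= j < shape[1] \
                            and 0 <= k < shape[2]:
                        out[di + pr, dj + pr, dk + pr] = arr[i, j, k]
        return out.ravel()

    votes = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    for idx in np.argwhere(np.asarray(candidate_mask) == 1):
        tp = patch(T, idx)
        mu_t, sig_t = tp.mean(), tp.std()
        dists, labs, window_labs = [], [], []
        for img, lab in entries:
            I = np.asarray(img, dtype=np.float64)
            L = np.asarray(lab)
            for di in range(-sr, sr + 1):
                for dj in range(-sr, sr + 1):
                    for dk in range(-sr, sr + 1):
                        c = (idx[0] + di, idx[1] + dj, idx[2] + dk)
                        inside = all(0 <= c[a] < shape[a] for a in range(3))
                        if not inside:
                            continue
                        centre_label = L[c]
                        window_labs.append(centre_label)
                        lp = patch(I, c)
                        mu_l, sig_l = lp.mean(), lp.std()
                        lum = (2 * mu_t * mu_l + C1) / (mu_t ** 2
                                                        + mu_l ** 2 + C1)
                        con = (2 * sig_t * sig_l + C2) / (sig_t ** 2
                                                          + sig_l ** 2 + C2)
                        if lum * con < preselection_threshold:
                            continue
                        dists.append(((tp - lp) ** 2).sum())
                        labs.append(centre_label)
        if dists:
            d = np.array(dists)
            h2 = d.min() + bandwidth_floor
            w = np.exp(-d / h2)
            v = float((w * np.array(labs)).sum() / w.sum())
        else:
            v = float(np.mean(window_labs))
        votes[tuple(idx)] = v
        labels[tuple(idx)] = 1 if v >= decision_threshold else 0
    return labels, votes


def bruteforce_anterior_split(mask, affine, y_cut=-12.0):
    """Per-voxel loop computing anterior/posterior counts in world mm."""
    n_ant = n_post = 0
    for idx in np.argwhere(np.asarray(mask) == 1):
        world = affine[:3, :3] @ idx + affine[:3, 3]
        if world[1] > y_cut:
            n_ant += 1
        else:
            n_post += 1
    return n_ant, n_post


def bruteforce_confusion(true_labels, predicted_labels):
    tp = fn = fp = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1:
            fn += 1
        elif p == 1:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn
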