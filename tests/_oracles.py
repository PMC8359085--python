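"""Independent brute-force references for the matrix texture features.

Everything here is written as plain nested loops over pixels, pairs and
runs, deliberately sharing no code with the package implementation, so it
can serve as an oracle on small planes.
"""

from __future__ import annotations

import math

import numpy as np

GLCM_NAMES = (
    "Inertia",
    "Correlation",
    "InverseDifferenceMoment",
    "ClusterShade",
    "ClusterProminence",
    "HaralickCorrelation",
)
GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GreyLevelNonuniformity",
    "RunLengthNonuniformity",
    "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis",
    "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis",
    "LongRunLowGreyLevelEmphasis",
    "LongRunHighGreyLevelEmphasis",
)


def brute_glcm(levels, roi, direction, distance=1, symmetric=True, ng=None):
    """Pairwise enumeration co-occurrence matrix; None if no pair exists."""
    ng = ng or int(levels.max())
    nr, nc = levels.shape
    dr, dc = direction
    counts = np.zeros((ng, ng))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr * distance, c + dc * distance
            if 0 <= r2 < nr and 0 <= c2 < nc and roi[r, c] and roi[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    if counts.sum() == 0:
        return None
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def brute_glcm_features(p):
    ng = p.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out = {}
    out["Inertia"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out["InverseDifferenceMoment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["ClusterShade"] = sum(
        (i + j + 2 - mu_i - mu_j) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["ClusterProminence"] = sum(
        (i + j + 2 - mu_i - mu_j) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
    )
    sum_ij = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    if var_i <= 0 or var_j <= 0:
        out["Correlation"] = 1.0
        out["HaralickCorrelation"] = 1.0
    else:
        out["Correlation"] = (sum_ij - mu_i * mu_j) / math.sqrt(var_i * var_j)
        marg = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
        mm = sum(marg) / ng
        mv = sum((m - mm) ** 2 for m in marg) / ng
        out["HaralickCorrelation"] = (sum_ij - mm * mm) / mv if mv > 0 else 1.0
    return out


def brute_glrlm(levels, roi, direction, ng=None, lmax=None):
    """Run counting by run-start detection and forward walking."""
    ng = ng or int(levels.max())
    nr, nc = levels.shape
    lmax = lmax or max(nr, nc)
    dr, dc = direction
    r_mat = np.zeros((ng, lmax), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if not roi[r, c]:
                continue
            pr, pc = r - dr, c - dc
            prev_same = (
                0 <= pr < nr
                and 0 <= pc < nc
                and roi[pr, pc]
                and levels[pr, pc] == levels[r, c]
            )
            if prev_same:
                continue  # not a run start
            length = 1
            nr_, nc_ = r + dr, c + dc
            while (
                0 <= nr_ < nr
                and 0 <= nc_ < nc
                and roi[nr_, nc_]
                and levels[nr_, nc_] == levels[r, c]
            ):
                length += 1
                nr_ += dr
                nc_ += dc
            r_mat[levels[r, c] - 1, length - 1] += 1
    return r_mat


def brute_glrlm_features(r_mat):
    ng, lmax = r_mat.shape
    n_runs = r_mat.sum()
    out = {name: 0.0 for name in GLRLM_NAMES}
    for g in range(ng):
        for l in range(lmax):
            cnt = r_mat[g, l]
            if cnt == 0:
                continue
            gv, lv = g + 1, l + 1
            out["ShortRunEmphasis"] += cnt / lv**2
            out["LongRunEmphasis"] += cnt * lv**2
            out["LowGreyLevelRunEmphasis"] += cnt / gv**2
            out["HighGreyLevelRunEmphasis"] += cnt * gv**2
            out["ShortRunLowGreyLevelEmphasis"] += cnt / (gv**2 * lv**2)
            out["ShortRunHighGreyLevelEmphasis"] += cnt * gv**2 / lv**2
            out["LongRunLowGreyLevelEmphasis"] += cnt * lv**2 / gv**2
            out["LongRunHighGreyLevelEmphasis"] += cnt * gv**2 * lv**2
    out["GreyLevelNonuniformity"] = sum(r_mat[g, :].sum() ** 2 for g in range(ng))
    out["RunLengthNonuniformity"] = sum(r_mat[:, l].sum() ** 2 for l in range(lmax))
    return {k: v / n_runs for k, v in out.items()}
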